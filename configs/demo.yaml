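# Bundled demo: 5 breeds x 20 individuals, 2 chromosomes x 30 Mb (~4,000 SNPs
# at 15 kb spacing), with planted heterozygous tracts, autozygous tracts and
# balancing windows so that every stage has signal to find.
schema: 1
seed: 7
output_dir: results/demo
simulate:
  n_breeds: 5
  individuals_per_breed: 20
  chromosomes: [30000000, 30000000]
  snp_spacing_bp: 15000
  breed_divergence: 0.10
  missing_rate: 0.02
  features:
    - {kind: HRR_TRACT, breed: breed1, chrom: "1", start_bp: 2000000, end_bp: 2599999, carrier_fraction: 0.8}
    - {kind: HRR_TRACT, breed: breed2, chrom: "1", start_bp: 9000000, end_bp: 9599999, carrier_fraction: 0.8}
    - {kind: HRR_TRACT, breed: breed3, chrom: "2", start_bp: 5000000, end_bp: 5599999, carrier_fraction: 0.8}
    - {kind: HRR_TRACT, breed: breed4, chrom: "2", start_bp: 14000000, end_bp: 14599999, carrier_fraction: 0.8}
    - {kind: HRR_TRACT, breed: breed5, chrom: "1", start_bp: 2000000, end_bp: 2599999, carrier_fraction: 0.8}
    - {kind: ROH_TRACT, breed: breed2, chrom: "2", start_bp: 20000000, end_bp: 22999999, carrier_fraction: 0.8}
    - {kind: ROH_TRACT, breed: breed4, chrom: "1", start_bp: 16000000, end_bp: 18999999, carrier_fraction: 0.8}
    - {kind: BALANCING_WINDOW, breed: breed1, chrom: "1", start_bp: 24000001, end_bp: 24250000}
    - {kind: BALANCING_WINDOW, breed: breed3, chrom: "2", start_bp: 9000001, end_bp: 9250000}
    - {kind: BALANCING_WINDOW, breed: breed5, chrom: "1", start_bp: 12000001, end_bp: 12250000}
qc:
  max_missing_marker: 0.10
  max_missing_sample: 0.10
  min_maf: 0.01
  per_breed_n: 20
hrr:
  min_snp: 20
  min_length_bp: 50000
  max_gap_bp: 50000
  max_opposite: 3
  max_missing: 1
hbd:
  rates: [2, 4, 8, 16, 32, 64]
  non_hbd_rate: 128
  error_rate: 0.001
  threshold: 0.5
  em_tol: 1.0e-6
  em_max_iter: 25
islands:
  top_percentile: 0.1
  min_snp: 2
tajima:
  window_bp: 250000
  top_fraction: 0.001
hotspots:
  z_crit: 1.645
factors: configs/demo_factors.tsv
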