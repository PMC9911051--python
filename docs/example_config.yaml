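# Example pipeline configuration for `popsplit report`.
# Simulate inputs first, e.g.:
#   popsplit simulate --pops EUR=8,ENA=8 --t-split 1000 --seed 101 \
#       --vcf-out sim.vcf --popmap-out sim.popmap
vcf: sim.vcf
popmap: sim.popmap
out_dir: report
max_missing_frac: 0.5
min_qual: 30.0
hwe_alpha: 1.0e-6
ld_window_bp: 50000
ld_r2_max: 0.5
groups:
  Europe: [EUR]
  NorthAmerica: [ENA]
f3_block_size: 500
fit_pairs:
  - [EUR, ENA]
fit_families: [no_migration, bidirectional]
fit_projection: 8
fit_genealogies: 200
mu: 4.0e-9
generation_time: 1.0
t_years_max: 7500
seed: 1
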