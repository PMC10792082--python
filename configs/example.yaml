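# Example pipeline configuration for `oralgut run --config configs/example.yaml`.
#
# Exactly one of `simulate` or `inputs` must be present:
#   simulate — generate a seeded synthetic cohort and analyse it (self-contained)
#   inputs   — analyse existing interchange TSVs
#
# All sections except that choice are optional; omitted keys take the
# defaults shown here.

output_dir: results/example_run

# Oral sites to pair against stool (non-empty subset of the four).
oral_sites: [saliva, buccal_mucosa, supragingival_plaque, tongue_dorsum]

simulate:
  n_subjects: 125           # one stool + one sample per oral site each
  n_oral_species: 40        # oral-adapted pool (includes the five marker species)
  n_gut_species: 60         # gut-adapted pool (never seen in oral samples)
  n_generalist_species: 10  # present in both niches at the native rates
  lognormal_mu: 0.0         # log-scale abundance magnitude parameters
  lognormal_sigma: 2.0
  occupancy_oral_in_oral: 0.9   # P(oral-pool species present | oral sample)
  occupancy_gut_in_gut: 0.95    # P(gut-pool species present | stool sample)
  occupancy_oral_in_gut: 0.3    # P(oral-pool species present | stool sample)
  n_markers_per_species: 100    # clade-specific markers per shared species
  gene_loss_prob: 0.02          # per-marker loss when deriving a strain (<= 0.1)
  marker_dropout_prob: 0.0      # per-marker detection failure (depth noise)
  n_shared_subjects: 7          # subjects planted with a shared stool/oral strain
  # shared_species defaults to the five frequently overlapping oral species:
  # Streptococcus_parasanguinis, Haemophilus_parainfluenzae,
  # Streptococcus_salivarius, Streptococcus_mitis, Veillonella_parvula
  seed: 17

# To analyse real tables instead, replace `simulate` with:
# inputs:
#   metadata: path/to/metadata.tsv      # sample_id, subject_id, body_site, study_id, visit
#   abundance: path/to/abundance.tsv    # sample_id, species, relative_abundance (percent)
#   markers: path/to/markers.tsv        # sample_id, marker_id, value (optional, for strains)
#   marker_map: path/to/marker_map.tsv  # marker_id, species

analysis:
  presence_threshold: 0.0       # percent; detection is strictly > threshold
  prevalence_min_fraction: 0.10 # keep species detected in >= max(count, ceil(frac*N)) samples
  prevalence_min_count: 3
  overlap_min_fraction: 0.10    # keep species overlapping in >= 10% of pairs (inclusive)
  q_threshold: 0.05             # BH-adjusted significance level (strict <)
  paired_test: true             # paired signed-rank; false -> unpaired rank-sum

strains:
  coverage_min: 0.9             # sample eligible when >= 90% of markers detected
  marker_presence_threshold: 0.0
  # species: [...]              # defaults to the five marker species above
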