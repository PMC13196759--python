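# photokin run configuration (photokin demo --config this_file.yaml)
# Every tunable has a recorded default; omitted keys fall back to these values.

seed: 0                     # top-level seed; all substreams derive from it

# behavioral assay schedule
acclimation_s: 1800.0       # dark acclimation before the first light epoch (s)
epoch_s: 300.0              # length of each light/dark epoch (s)
n_cycles: 3                 # light+dark cycle pairs after acclimation
frame_rate: 25.0            # tracking frame rate (Hz)

# imaging schedule
imaging_acclimation_s: 60.0 # no-light lead-in (s); also the dF/F baseline window
imaging_epoch_s: 30.0       # ON/OFF epoch length (s)
imaging_n_cycles: 4
imaging_frame_rate: 5.0     # trace sampling rate (Hz)

# locomotor scoring
bin_s: 30.0                 # activity bin width (s)
window_bins: 1              # bins each side of a transition
jitter_mm: 0.1              # centroid steps below this are zeroed (mm)
denom_epsilon: 1.0e-06      # |delta sum| below this flags the fish invalid (mm)

# thresholds
dead_band: 0.05             # ON/OFF preference dead-band (dF/F)
q_level: 0.05               # BH FDR level for the screen and the map
max_clusters: 5             # flat clusters cut from the tuning dendrogram

# synthetic cohorts
n_per_population: 12        # fish per parental/F1 population
n_f2: 60                    # F2 fish
n_loci: 4                   # additive loci in the cross model
env_sd: 0.06                # environmental noise on the genetic value

# activity-map phantom
phantom_shape: [24, 24, 12] # voxel grid
phantom_n_per_group: 6      # volumes per group

out_dir: photokin_run       # output directory (excluded from the config hash)
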