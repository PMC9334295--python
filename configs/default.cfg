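# colonynet pipeline configuration (flat key = value; '#' starts a comment)

# --- input ----------------------------------------------------------------
# preset: minimal | dose_series | matched_pair | none
#   minimal      2 doses x small field, quick smoke runs
#   dose_series  five doses (0,2,4,6,8 Gy), H460-like counts and morphology
#   matched_pair uniform "0 Gy" vs clustered "8 Gy" at equal cell count
#   none         read user images from input_dir (<line>/<dose>Gy/*.tif or
#                flat <line>_<dose>Gy_<rep>.tif)
preset = minimal
input_dir =
line = SYN
images_per_dose = 3
seed = 1

# --- segmentation ---------------------------------------------------------
filter_window_px = 3        # adaptive noise filter window (odd)
min_component_px = 8        # components with fewer pixels are removed (strict <)
connectivity = 8            # 4 or 8
hmin_depth = 2.0            # h-minima imposition depth on the distance relief
clear_border = true         # suppress structures touching the image border

# --- Waxman graph ---------------------------------------------------------
alpha = 1.0
beta = 0.025
R = 0.05                    # cut-off; 0.1 / 0.05 / 0.02 <-> p = 0.9 / 0.95 / 0.98
L = per_image               # 'per_image' or a fixed pixel distance

# --- topology -------------------------------------------------------------
er_replicates = 20          # Erdos-Renyi G(n,m) draws per image

# --- statistics -----------------------------------------------------------
alpha_level = 0.05
welch = false               # true -> Welch instead of pooled-variance Student
test_metrics = sw,area      # per-image metrics tested against the 0 Gy group
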