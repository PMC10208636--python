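"""Centralised default analysis parameters.

Every numeric default used across the analysis stages lives here so that
a run is fully characterised by this table plus the per-run overrides.
Units are stated per entry.
"""

# --- Welch spectral estimation ---
WELCH_NPERSEG = 1024          # samples per Hann window
WELCH_OVERLAP = 0.5           # fractional overlap
SPECTRUM_FMIN = 1.0           # Hz
SPECTRUM_FMAX = 150.0         # Hz
SPECTRUM_DF = 0.25            # Hz, grid spacing (zero-padded FFT)

# --- aperiodic/periodic spectral parametrization ---
PARAM_FIT_RANGE = (1.0, 200.0)   # Hz
PARAM_FIT_DF = 0.5               # Hz, fit-grid resolution
PEAK_WIDTH_LIMITS = (0.5, 12.0)  # Hz
PEAK_THRESHOLD = 2.0             # multiples of residual SD
MIN_PEAK_HEIGHT = 0.0            # log10 power
MAX_N_PEAKS = 20                 # hard cap (termination guarantee)

# --- sorted spectral-density map ---
SORT_BAND = (20.0, 30.0)      # Hz, segment sort key band
N_SORT_BINS = 50              # quantile bins

# --- state contrast ---
CONTRAST_ALPHA = 0.05         # FDR level

# --- bout detection (BOSC) ---
WAVELET_CYCLES = 6            # Morlet width
BOUT_DURATION_CYCLES = 3      # duration threshold in cycles
BOUT_AMPLITUDE_PCT = 95.0     # chi-square percentile for amplitude threshold
BOUT_FREQS_MIN = 2.0          # Hz, default log-spaced grid
BOUT_FREQS_MAX = 128.0        # Hz
BOUT_N_FREQS = 29
KDE_BW_THETA_MS = 50.0        # duration KDE bandwidth, theta band
KDE_BW_GAMMA_MS = 10.0        # duration KDE bandwidth, gamma band

# --- cross-frequency coupling ---
COMOD_MIN_WINDOWS = 30
N_PERMUTATIONS = 5000         # surrogate count (scalable per run)
CLUSTER_ALPHA = 0.05
ROBUST_FRACTION = 0.8         # "significant in >=80% of samples"
ENVELOPE_BANDWIDTH = 2.0      # Hz, Butterworth bandpass width
ENVELOPE_FILTER_ORDER = 3
BICOH_F1_MAX = 75.0           # Hz
BICOH_F2_MAX = 150.0          # Hz
BICOH_SEGLEN = 1024           # samples

# --- SWR detection ---
SWR_BAND = (100.0, 250.0)           # Hz, ripple band
HIGH_GAMMA_BAND = (80.0, 120.0)     # Hz
HFO_BAND = (110.0, 160.0)           # Hz
SWR_THRESHOLD_SD = 3.0
SECONDARY_THRESHOLD_SD = 1.0        # high gamma / HFO peak threshold
EDGE_THRESHOLD_SD = 1.0
SWR_MIN_DURATION = 0.050            # s
SWR_MERGE_GAP = 0.125               # s
ENVELOPE_SMOOTH_BAND = (1.0, 20.0)  # Hz, secondary bandpass of rectified z

# --- spike-field coherence ---
SFC_CYCLES = 5                # Hann window length in cycles per frequency
SFC_FMIN = 2.0                # Hz
SFC_FMAX = 200.0              # Hz
SFC_DF = 1.0                  # Hz
N_SPIKE_SHUFFLES = 1000
PPC_PEAK_HEIGHT = 0.005
PPC_PEAK_PROMINENCE = 0.005
PREFERRED_KDE_BW = 4.0        # Hz
SWR_WINDOW = 0.600            # s, window centered on SWR events
MIN_SWR_SPIKES = 20
SFC_BANDS = ((2, 3), (4, 10), (11, 20), (21, 40), (41, 100), (101, 200))
N_REASSIGNMENTS = 1000

# --- rhythmicity ---
ACG_BINSIZE = 0.010           # s
ACG_MAX_LAG = 0.500           # s
ACG_NORM_WINDOW = (0.100, 0.150)  # s, normalisation lag window
ACG_MIN_COUNTS = 100
OMEGA_BOUNDS = (4.0, 10.0)    # Hz
C_BOUNDS = (0.0, 0.2)
TAU1_BOUNDS = (0.01, 5.0)     # s
TAU2_BOUNDS = (0.0, 0.05)     # s
OMEGA_STARTS = (4.5, 6.0, 7.5, 9.0)  # Hz, multi-start grid
B_FLOOR = 1e-3                # offset floor when forming the a/b index
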