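"""Physical constants and package-wide defaults (CG membrane conventions)."""

#: Boltzmann constant in kJ mol^-1 K^-1.
KB = 0.0083145

#: Default simulation temperature (K) for two-lipid bilayer systems.
DEFAULT_TEMPERATURE = 310.0

#: Temperature (K) used for phase-separated (raft) membranes.
RAFT_TEMPERATURE = 290.0

#: Default protein/lipid contact cutoff (nm).
CONTACT_CUTOFF_NM = 0.55

#: Default number of k-means microstates for (theta_t, theta_r) discretization.
DEFAULT_N_MICROSTATES = 400

#: Default MSM/HMM lag time (ns), where implied timescales plateau.
DEFAULT_LAG_NS = 450.0

#: Default free-energy-surface binning over (theta_t, theta_r).
DEFAULT_FES_BINS = (70, 70)

#: Default trajectory stride (ns) of the coarse-grained trajectories.
DEFAULT_STRIDE_NS = 15.0
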