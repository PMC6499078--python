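# Annotated simulation spec for `suma simulate --spec simulation_spec.yaml`.
# Fields mirror sumaerr.SimulationSpec; omitted fields use the defaults.

n_pred: 2000          # predictions (rows)
n_ens: 120            # ensemble replicates (columns); >= 2

# Base variance components of the SUMA model.
sigma_sm2: 0.0003     # shared multiplicative (global factor, one draw/replicate)
sigma_m2: 0.0075      # unshared multiplicative (per prediction per replicate)
sigma_sa2: 0.0        # shared additive
sigma_a2: 0.0         # unshared additive

# Error-free exposure distribution (ppb).
z_dist: uniform       # uniform -> z_params are (low, high);
z_params: [10.0, 100.0]  # lognormal -> (mean of log, sd of log)

# Spatial extent in projected planar meters: [x0, y0, x1, y1].
extent: [0.0, 0.0, 200000.0, 150000.0]

# Error family for the multiplicative draws (mean re-parameterized to 1):
# lognormal (default) or gamma.
error_family: lognormal

# Clip simulated exposures at zero (default false: estimator assumptions
# stay exact when negative additive excursions are retained).
truncate_negative: false

seed: 0               # overridden by --seed on the command line
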