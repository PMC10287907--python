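"""Simulate a small SuRE library, fit the model, and check recovery.

Generates a 4 kb genome with three planted regulatory elements, draws a
fragment library from the Poisson count model, tunes the elastic-net
penalties by held-out likelihood, runs the two-step fit, and compares the
fitted per-bp coefficient track with the planted truth.
"""

import numpy as np

import suredec as sd

config = sd.SimulationConfig(
    genome_length=4000,
    n_fragments=3000,
    fragment_length_range=(100, 300),
    spikes=[
        sd.Spike(800, 860, 0.05, "+"),    # activating element
        sd.Spike(2200, 2250, -0.05, "+"), # repressive element
        sd.Spike(1500, 1550, 0.05, "-"),  # minus-strand activator
    ],
    seed=42,
)
truth = sd.simulate_truth(config)
elements = sd.simulate_library(truth, config)
print(f"simulated {len(elements)} fragments, "
      f"mean reporter count {np.mean([e.cdna_count for e in elements]):.2f}")

blocks = sd.partition_blocks(elements)
bins = sd.build_bins(blocks[0].elements, "+")
stats = sd.bin_stats(bins)
print(f"plus strand: {stats['count']} bins, median width {stats['median_length']:.0f} bp")

tune = sd.tune_penalties(blocks, alpha_grid=[0.01, 0.1], n_lambda=20,
                         lambda_min_ratio=1e-3, seed=42)
print(f"tuned penalties: alpha*={tune.alpha:g}, lambda*={tune.lam:.4g} "
      f"(held-out log-likelihood selection)")

fits, theta_bar = sd.two_step_fit(blocks, tune.alpha, tune.lam)
track = sd.merge_block_fits(fits, theta_bar.theta_L)
report = sd.recovery_report(truth, track, theta_bar, config)
print(f"per-bp Pearson(truth, fitted) = {report['track_pearson']:.3f} "
      f"over {report['n_positions']} covered positions")
print(f"length coefficient: true {config.theta_L:g}, "
      f"fitted {theta_bar.theta_L:.5f} "
      f"(abs error {report['theta_L_abs_error']:.2g})")
print(f"all planted element signs recovered: "
      f"{all(report['spike_sign_recovered'].values())}")
# A correlation well above 0 with matching spike signs means the fit
# localized the planted activating/repressive sequence; theta_L close to
# its true value means the length bias was cleanly separated from the
# spatial signal.
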