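"""Relative fitness from AUC ratios in simulated 1:1 competition assays.

Two experiments: (a) a tagged strain against its untagged isogenic twin —
the expected relative AUC is 0.5, since identical competitors split the
shared resource evenly; (b) the same strain against a stronger competitor
(competition coefficient 1.6 on the focal), which pushes the ratio well
below 0.5.  Groups are compared with one-way ANOVA and a Bonferroni
post-hoc test against the monoculture.
"""

import numpy as np

import fluogrowth as fg
from fluogrowth.simulate import _strain_from_params

t_grid = np.arange(0.0, 48.001, 0.25)
params = fg.default_params()


def run(layout, models, noise, title):
    ts, _, _ = fg.simulate_plate(layout, models, noise, t_grid)
    for channel in ts.channels:
        ts, _ = fg.blank_correct(ts, layout, channel)
    _, anova, table = fg.fitness_from_metrics(
        fg.metrics_table(ts, layout), "Pe_red", "red", "monoculture"
    )
    print(title)
    for _, row in table.iterrows():
        print(f"  {row['condition']:<14} mean relative AUC = "
              f"{row['mean_ratio']:.3f} (sd {row['sd_ratio']:.3f}, "
              f"n={row['n_replicates']})")
    print(f"  ANOVA F = {anova.f_statistic:.1f}, p = {anova.p_value:.2e}; "
          f"coculture vs monoculture Bonferroni p = {anova.posthoc[0][2]:.2e}")


# (a) isogenic competition: ratio ~ 0.5
layout, models, noise = fg.isogenic_competition_design(seed=30)
run(layout, models, noise, "Pe_red vs isogenic wild type:")

# (b) a stronger competitor suppresses the focal strain further
focal = _strain_from_params("Pe_red", "red", params)
comp = _strain_from_params("Sp_wt", None, params)
layout, models, noise = fg.competition_design(
    focal, comp, alpha=[[1.0, 1.6], [1.0, 1.0]], seed=30
)
run(layout, models, noise, "Pe_red vs stronger competitor (alpha 1.6):")
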