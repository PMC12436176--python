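"""Cohort simulation: classification plus ANOVA group comparison.

Simulates small cavovarus (CV), equinovarus (EV) and typically developing
(TD) cohorts, classifies every foot with the early-stance slope rule,
summarizes each foot's medial arch over the gait cycle, and compares the
groups with the one-way ANOVA + within-family Bonferroni procedure.
"""

import numpy as np
import pandas as pd

from hffm import (
    GaitWaveformConfig,
    anova_bonferroni,
    apply_deformity_preset,
    classify_foot_type,
    compute_angle_trajectories,
    generate_trial,
    group_summary_table,
    make_template_foot,
    normalize_to_cycle,
    summarize_curve,
)
from hffm.stats import GroupedOutcomes
from hffm.synthetic import realize_template

template = make_template_foot("R")
rows, labels = [], {}
for group in ("CV", "EV", "TD"):
    labels[group] = []
    for foot in range(5):
        cfg = apply_deformity_preset(
            GaitWaveformConfig(noise_sd_mm=1.0, n_cycles=3, seed=100 * foot + 1),
            group,
        )
        traj, _, events = generate_trial(template, cfg)
        rec = compute_angle_trajectories(
            traj, realize_template(template, cfg).neutral_frame()
        )
        label, _ = classify_foot_type(
            normalize_to_cycle(rec["hindfoot_shank_flexion"], events)
        )
        labels[group].append(label)
        row = summarize_curve(
            normalize_to_cycle(rec["medial_arch"], events, "medial_arch")
        )
        rows.append({"group": group, "foot": f"{group}{foot}",
                     "angle": "medial_arch", "mean": row.mean,
                     "max": row.max, "rom": row.rom})

print("Early-stance slope classification (EV = forefoot-first contact):")
for group, found in labels.items():
    print(f"  {group}: {found}")

g = GroupedOutcomes(pd.DataFrame(rows))
print("\nMedial arch by group (mean +/- SD across feet, degrees):")
print(group_summary_table(g).to_string(index=False, float_format="%.1f"))

tables = anova_bonferroni(g)
print("\nANOVA with within-family Bonferroni (family = mean/max/ROM):")
print(tables.omnibus.to_string(index=False, float_format="%.3g"))

print("""
EV feet classify as EV (positive hindfoot flexion slope at initial contact)
while CV and TD feet do not, and the medial arch separates the groups
(EV < CV < TD, smaller angle = higher arch), so the mean and max rows are
strongly significant while ROM, which the presets leave untouched, is not.""")
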