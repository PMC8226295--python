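"""Per-cell diurnal phase from a single snapshot (molecular timetable).

Simulates a culture whose cells sit at different points of a 24-h
transcriptional cycle (von Mises around 6 h after dawn), builds the 13
non-overlapping phase-bin gene sets from the known gene peak phases,
scores each bin in each cell, and reads every cell's internal time off
its 13-bin score profile. The recovered phases are compared with the
simulation's hidden truth.
"""
import numpy as np

import chronocell as cc
from chronocell.circular import circular_mae_hours

cfg = cc.SimConfig(
    n_cells_per_sample=2000,
    n_genes=3000,
    frac_rhythmic=0.2,        # 600 genes carry a diurnal phase
    amplitude=1.0,            # log-scale cosine amplitude
    cell_phase_kappa=4.0,     # concentrated population, mean 6 h after dawn
    sample_names=("Fe+",),
    mean_umis_per_cell=3300.0,
    seed=1,
)
matrix, truth = cc.simulate(cfg)
norm = cc.normalize_log(cc.filter_cells(matrix))

bins = cc.build_phase_bins(cc.make_phase_table(truth))
psm = cc.phase_scores(norm, bins, seed=0)
calls = cc.call_phase(psm, method="timetable")

true_phase = truth.cells.loc[norm.barcodes, "true_phase"].to_numpy()
ok = calls["phase_hat"].notna().to_numpy()
mae = circular_mae_hours(calls["phase_hat"].to_numpy(float)[ok], true_phase[ok])

print(f"cells called: {int(ok.sum())}/{len(ok)}")
print(f"circular MAE vs hidden truth: {mae:.2f} h")
print(f"dawn (0 h) vs cycle-end (24 h) column correlation: "
      f"{np.corrcoef(psm[0], psm[24])[0, 1]:.2f}")
print()
print("Each cell's phase is inferred from one snapshot, no time course")
print("needed; the high 0 h/24 h correlation confirms the scores wrap")
print("around the full 24-h cycle as they should.")
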