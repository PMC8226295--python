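"""Detecting a clock delay between culture conditions.

Iron-starved cells run their diurnal program late relative to replete
cells. This script injects a 2-h delay into the simulated Fe- sample,
calls per-cell phases in both samples, and estimates the shift with a
label-permutation test on the circular mean difference.
"""
import chronocell as cc

cfg = cc.SimConfig(
    n_cells_per_sample=500,
    n_genes=1500,
    frac_rhythmic=0.25,
    amplitude=1.0,
    cell_phase_kappa=4.0,
    phase_delay=2.0,          # hours added to every Fe- cell's phase
    delay_sample="Fe-",
    mean_umis_per_cell=3300.0,
    seed=2,
)
matrix, truth = cc.simulate(cfg)
norm = cc.normalize_log(cc.filter_cells(matrix))

psm = cc.phase_scores(norm, cc.build_phase_bins(cc.make_phase_table(truth)), seed=0)
calls = cc.call_phase(psm, method="timetable")

res = cc.phase_shift(
    calls.loc[norm.sample == "Fe+", "phase_hat"].to_numpy(float),
    calls.loc[norm.sample == "Fe-", "phase_hat"].to_numpy(float),
    n_perm=1000,
    seed=0,
)
print(f"estimated shift Fe- minus Fe+: {res['delta_hours']:+.2f} h "
      f"(injected: +2.00 h)")
print(f"permutation p-value: {res['p_value']:.4g} ({res['n_perm']} permutations)")
print(f"group circular means: Fe+ {res['mean_a']:.2f} h, Fe- {res['mean_b']:.2f} h")
print()
print("A positive shift with small p indicates the deficient culture's")
print("internal clock lags the replete one.")
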