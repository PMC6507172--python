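"""Run a reduced version of the two-subgroup clustering simulation.

Case 1: two five-set subgroups straddle the Meet/Min merge boundary, but PPIs
occur only within each subgroup — a network-aware distance should keep them
apart.  For each trial the MM matrix is clustered at cutoff 0.5 and the pMM
cutoff is percentile-matched within the trial.  The table counts, per
measure, how often the subgroups were merged into one cluster, cleanly
separated, or neither (imperfect).  100 trials keep this quick; the full
study uses 500.
"""

from pmmclust import SimulationConfig, conditional_counts, run_trials, summarize_trials

cfg = SimulationConfig(n_trials=100, seed=0)
trials = run_trials(1, cfg, measures=("MM", "pMM"))
print(summarize_trials(trials).to_string())

cond = conditional_counts(trials, "MM", "MERGED", "pMM")
total = int(cond.sum())
if total:
    print(
        f"\nAmong the {total} trials merged under MM, pMM separated "
        f"{cond['SEPARATED']} ({100 * cond['SEPARATED'] / total:.1f}%) — the PPI "
        "weighting recovers the subgroup structure that pure overlap misses."
    )
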