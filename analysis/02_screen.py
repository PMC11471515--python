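#!/usr/bin/env python
"""Forward MR screen on a small synthetic exposure panel.

Builds a five-exposure panel (the causal exposure from 01 plus four null
exposures), screens it against the simulated outcome with all five
estimators, Cochran's Q, MR-PRESSO and leave-one-out, applies BH-FDR
tiering, and writes the per-outcome report table under results/screen/.
Run 01_simulate_cohorts.py first.
"""

from pathlib import Path

from mrmediate.pipeline import AnalysisConfig, run_screen
from mrmediate.simulate import SimulationConfig, simulate_summary_stats
from mrmediate.summstats import concat_datasets, read_summary_stats

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240930


def main() -> None:
    exposure = read_summary_stats(ROOT / "simulated" / "exposure.tsv",
                                  trait_name="causal_exposure")
    outcome_causal = read_summary_stats(ROOT / "simulated" / "outcome.tsv",
                                        trait_type="binary", trait_name="outcome")
    nulls, null_outcomes = [], []
    for j in range(4):
        ne, _, no, _ = simulate_summary_stats(SimulationConfig(seed=SEED + 1 + j))
        ne.trait_name = f"null_exposure_{j + 1}"
        nulls.append(ne)
        null_outcomes.append(no)
    # one pooled outcome GWAS covering every exposure's instrument loci
    outcome = concat_datasets("outcome", "binary", [outcome_causal] + null_outcomes)

    cfg = AnalysisConfig(seed=SEED, out_dir=str(ROOT / "screen"))
    rows = run_screen(cfg, exposures=[exposure] + nulls, outcomes=[outcome])

    ivw_rows = [r for r in rows if r.method == "ivw"]
    print(f"{len(rows)} report rows ({len(ivw_rows)} exposures) -> {cfg.out_dir}")
    for r in sorted(ivw_rows, key=lambda r: r.pval):
        print(f"  {r.exposure:18s} OR={r.or_:.3f} p={r.pval:.2E} "
              f"P_FDR={r.p_fdr:.2E} tier={r.tier}")


if __name__ == "__main__":
    main()
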