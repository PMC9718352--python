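"""Fit the hierarchical Bernoulli-beta model to each synthetic cohort.

Reads the cohorts written by 01_simulate_cohorts.py (runs it if needed),
fits the group-level preference mu per experiment and writes the posterior
summaries (mean, 95% HDI, R-hat, ESS) to results/bayes_fits.json.
"""

import json
import runpy
from pathlib import Path

from dreadchoice import DESIGNS, RunConfig, load_trials
from dreadchoice.pipeline import fit_cohort

ROOT = Path(__file__).resolve().parents[1]
COHORTS = ROOT / "results" / "cohorts"
OUT = ROOT / "results" / "bayes_fits.json"
SEED = 20221130


def main() -> None:
    if not COHORTS.exists():
        runpy.run_path(str(ROOT / "analysis" / "01_simulate_cohorts.py"), run_name="__main__")
    config = RunConfig(seed=SEED)
    payload = {}
    for exp_id, design in DESIGNS.items():
        table = load_trials(COHORTS / f"experiment{exp_id}_binomial.csv", design)
        summary = fit_cohort(table, config)
        lo, hi = summary.mu.hdi
        payload[str(exp_id)] = summary.to_dict()["mu"]
        verdict = "excludes" if not lo <= 0.5 <= hi else "includes"
        print(f"experiment {exp_id}: mu = {summary.mu.mean:.3f}, "
              f"95% HDI ({lo:.3f}, {hi:.3f}) — {verdict} indifference; "
              f"R-hat {summary.mu.rhat:.3f}, ESS {summary.mu.ess:.0f}")
    OUT.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
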