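"""Frequentist test battery on the synthetic cohorts.

Per experiment: the one-sample two-tailed t-test of per-rat choice
percentages against the 50% chance level, then the two repeated-measures
ANOVAs — trial block (free trials 1-8 vs 9-16) x session, and session
block (sessions 1-5 vs 6-10) x session order within block.  Writes
results/nhst.json.
"""

import json
import runpy
from pathlib import Path

from dreadchoice import DESIGNS, block_aggregate, choice_fractions, load_trials, one_sample_t, rm_anova

ROOT = Path(__file__).resolve().parents[1]
COHORTS = ROOT / "results" / "cohorts"
OUT = ROOT / "results" / "nhst.json"


def main() -> None:
    if not COHORTS.exists():
        runpy.run_path(str(ROOT / "analysis" / "01_simulate_cohorts.py"), run_name="__main__")
    payload = {}
    for exp_id, design in DESIGNS.items():
        table = load_trials(COHORTS / f"experiment{exp_id}_binomial.csv", design)
        fr = [s.fraction_target for s in choice_fractions(table) if s.fraction_target is not None]
        tt = one_sample_t(fr)
        print(f"experiment {exp_id}: mean {tt.mean:.2f}% ± {tt.sem:.2f} (SEM), "
              f"t({tt.df}) = {tt.t:.2f}, p = {tt.p:.4g}")
        entry = {"ttest": tt.to_dict(), "anova": {}}
        for blocking in ("trial_block", "session_block"):
            cells = block_aggregate(table, blocking)
            res = rm_anova(cells)
            entry["anova"][blocking] = res.to_dict()
            eff = res.effects["a"]
            print(f"  {blocking}: block main effect F({eff.df_num:g},{eff.df_den:g}) = "
                  f"{eff.F:.3f}, p = {eff.p:.3f}, partial eta^2 = {eff.eta_sq:.3f}")
        payload[str(exp_id)] = entry
    OUT.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
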