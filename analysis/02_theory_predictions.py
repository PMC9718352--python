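"""Qualitative predictions of the three value theories for each experiment.

Evaluates the documented reference parameterization of every theory over
the three designs and prints which arm each theory prefers — the aversive
discounting theory favors late shocks (LL in experiment 1), the utility
from anticipation theory favors early shocks (EL in experiment 1, EE in 2),
both favor the early reward in experiment 3, and the spill-over account
reproduces the observed pattern (EL, indifference, anti-EE).  Writes
results/theory_predictions.json.
"""

import json
from pathlib import Path

from dreadchoice import DESIGNS, REFERENCE_PARAMS, option_utility, predict_preferences

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    payload = {}
    for theory, params in REFERENCE_PARAMS.items():
        preds = predict_preferences(params)
        payload[theory] = {str(k): v for k, v in preds.items()}
        print(f"{theory}:")
        for exp_id, design in DESIGNS.items():
            u_a = option_utility(design.option_a, params)
            u_b = option_utility(design.option_b, params)
            print(f"  experiment {exp_id}: {preds[exp_id]:>12s}  "
                  f"(U_{design.option_a.label} = {u_a:+.3f}, U_{design.option_b.label} = {u_b:+.3f})")
    (OUT / "theory_predictions.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"\nwrote {OUT / 'theory_predictions.json'}")


if __name__ == "__main__":
    main()
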