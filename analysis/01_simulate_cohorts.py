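"""Generate the synthetic cohorts for all three experiments.

Fixed-rate cohorts at the group sizes of the three experiments (25/20/21
rats, 10 sessions x 6 forced + 16 free trials) with the per-experiment
omission rates, plus one agent-mode cohort per value theory for
experiment 1.  Writes trial CSVs under results/cohorts/.
"""

from pathlib import Path

from dreadchoice import (
    DESIGNS,
    GROUP_SIZES,
    REFERENCE_PARAMS,
    CohortSpec,
    choice_fractions,
    generate_binomial_cohort,
    simulate_experiment,
    write_trials,
)
from dreadchoice.synthetic_data import DEFAULT_OMISSION_RATES
from dreadchoice.value_models import with_temperature

OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"
SEED = 20221130

# per-experiment choice rates mirroring the published group means
RATES = {1: 0.55, 2: 0.52, 3: 0.45}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for exp_id, design in DESIGNS.items():
        spec = CohortSpec(
            n_subjects=GROUP_SIZES[exp_id],
            p_choice=RATES[exp_id],
            omission_rate=DEFAULT_OMISSION_RATES[exp_id],
            seed=SEED + exp_id,
        )
        table = generate_binomial_cohort(spec, design)
        path = OUT / f"experiment{exp_id}_binomial.csv"
        write_trials(table, path)
        fr = [s.fraction_target for s in choice_fractions(table)]
        mean = sum(fr) / len(fr)
        print(f"experiment {exp_id}: {len(table)} trials, "
              f"mean target choice {mean:.1f}% (generating rate {RATES[exp_id]:.0%})")

    for theory, params in REFERENCE_PARAMS.items():
        spec = CohortSpec(n_subjects=GROUP_SIZES[1], seed=SEED + 10)
        table = simulate_experiment(DESIGNS[1], with_temperature(params, 1.0), spec)
        path = OUT / f"experiment1_agent_{theory}.csv"
        write_trials(table, path)
        fr = [s.fraction_target for s in choice_fractions(table)]
        print(f"agent {theory} (exp 1): mean EL choice {sum(fr)/len(fr):.1f}%")


if __name__ == "__main__":
    main()
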