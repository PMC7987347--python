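#!/usr/bin/env python
"""Generate the study datasets: the cross-species survey (nine
wild/domesticated dyads plus primate cohorts) and the two longitudinal
experiments (reciprocal diet; colonization), written in the plain-text
formats every later stage reads."""

import argparse
from pathlib import Path

from wilddom.simulate import LongitudinalBlock, SyntheticSpec, generate, generate_longitudinal, write_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    survey = generate(SyntheticSpec(include_primates=True, seed=args.seed))
    write_dataset(survey, args.out_dir / "survey")
    print(f"survey: {survey.counts.shape[0]} samples x {survey.counts.shape[1]} taxa, "
          f"{survey.metadata['dyad_id'].nunique() - 1} dyads + primates")

    diet = generate_longitudinal(
        SyntheticSpec(seed=args.seed + 1, longitudinal=LongitudinalBlock(kind="diet"))
    )
    write_dataset(diet, args.out_dir / "diet_experiment")
    print(f"diet experiment: {diet.counts.shape[0]} samples, "
          f"{diet.metadata['individual_id'].nunique()} individuals")

    colonization = generate_longitudinal(
        SyntheticSpec(seed=args.seed + 2, longitudinal=LongitudinalBlock(kind="colonization"))
    )
    write_dataset(colonization, args.out_dir / "colonization_experiment")
    print(f"colonization experiment: {colonization.counts.shape[0]} samples "
          f"(incl. the wild donor)")


if __name__ == "__main__":
    main()
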