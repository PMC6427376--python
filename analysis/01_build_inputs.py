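#!/usr/bin/env python
"""Assemble the model inputs and write them under results/inputs/.

Three files drive every later step: the per-sex intake summary table
(published survey means/SEs, one 18-81 band per sex), a synthetic
registry-style mortality table whose sex totals per disease class equal the
published 2016 figures exactly, and the editable dose-response parameter
file (placeholder values, clearly tagged). A miniature fixture
configuration goes to results/inputs/mini/ for quick experiments.
"""

import argparse
import json
from pathlib import Path

from primesim.io import (
    load_configuration,
    packaged_parameters_path,
    write_intake_csv,
    write_mortality_csv,
    write_parameters,
)
from primesim.synthetic import (
    default_intake_distributions,
    default_mortality_spec,
    generate_mortality_table,
    make_test_fixture,
)
from primesim.domain import AgeBand


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    band = AgeBand(18, 81)
    write_intake_csv(default_intake_distributions(age_band=band), out / "intake.csv")
    from primesim.synthetic import SyntheticMortalitySpec

    spec = SyntheticMortalitySpec(
        totals=default_mortality_spec(seed=args.seed).totals,
        age_bands=(band,),
        seed=args.seed,
    )
    write_mortality_csv(generate_mortality_table(spec), out / "mortality.csv")
    payload = json.loads(packaged_parameters_path().read_text())
    write_parameters(payload, out / "parameters.json")

    config = load_configuration(
        out / "intake.csv", out / "mortality.csv", out / "parameters.json"
    )
    make_test_fixture(args.seed, out / "mini")

    print(f"wrote inputs to {out}")
    print(
        f"configuration: {len(config.components)} components, "
        f"{len(config.strata)} strata, "
        f"{config.mortality.total()} deaths in scope, "
        f"provenance={config.provenance}"
    )


if __name__ == "__main__":
    main()
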