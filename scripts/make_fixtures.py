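"""Regenerate the small per-scenario fixture datasets under tests/fixtures/.

Run from the repository root:

    python scripts/make_fixtures.py

One tidy CSV per tabulated condition, triplicate, cv = 0.05, with full
provenance embedded so tests can verify exact regeneration.
"""

from pathlib import Path

from maillard_kinetics import NoiseModel, generate_dataset, write_dataset
from maillard_kinetics.synthetic_data import SCENARIO_IDS, table1_scenario

FIXTURE_DIR = Path(__file__).resolve().parent.parent / "tests" / "fixtures"


def main() -> None:
    FIXTURE_DIR.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(SCENARIO_IDS):
        sc = table1_scenario(sid)
        ds = generate_dataset(sc.spec, sc.k, NoiseModel(cv=0.05, seed=100 + i), n_replicates=3)
        out = FIXTURE_DIR / f"{sid}.csv"
        write_dataset(ds, out)
        print(f"wrote {out}")


if __name__ == "__main__":
    main()
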