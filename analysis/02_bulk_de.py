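"""Run the bulk DE engine over the simulated infection experiment.

Fits every contrast family the signature rules need (per-infection T_FH vs
T_eff, the combined contrast, T_FR contrasts, and one-vs-rest across
infections) and writes the DE tables plus directional-call summaries under
results/bulk_de/.
"""

from pathlib import Path

import pandas as pd

from fhsig import workflow
from fhsig.io import read_counts, read_table, write_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = read_counts(ROOT / "simulated" / "bulk" / "counts.tsv")
    meta = read_table(ROOT / "simulated" / "bulk" / "samples.tsv")
    out = ROOT / "bulk_de"
    out.mkdir(parents=True, exist_ok=True)

    outputs = workflow.run_bulk_de(counts, meta)
    for name, table in outputs.results.items():
        write_table(table, out / f"de_{name.replace(':', '_')}.tsv")

    summary = pd.DataFrame(
        {
            cond: {
                "n_up": int((calls == 1).sum()),
                "n_down": int((calls == -1).sum()),
            }
            for cond, calls in outputs.tfh_vs_teff.items()
        }
    ).T
    write_table(summary, out / "tfh_vs_teff_call_counts.tsv")
    print("directional calls (T_FH vs T_eff) per infection:")
    print(summary.to_string())
    comb = outputs.tfh_vs_teff_combined
    print(f"combined contrast: {(comb == 1).sum()} up, {(comb == -1).sum()} down "
          f"of {len(comb)} genes tested")


if __name__ == "__main__":
    main()
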