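#!/usr/bin/env python
"""Fit the learning-model competition to a deposited per-decision spreadsheet.

The published per-animal source data ("each individual animal's decisions in
temporal sequence") can be exported to a delimited table or Excel sheet with
one decision per row.  This script ingests such a file, builds the per-larva
(dose, preference, decision-count) table for the post-training phase, fits
the requested model variants, and writes the comparison table
(k, delta log P, delta AIC, delta BIC) plus the per-dose untrained-fraction
curve with profile intervals.

The expected semantic columns are larva_id, group, n_cycles, phase,
decision_index, outcome (approach/avoid); if the spreadsheet uses different
column names, supply a YAML column map, e.g.::

    larva_id: Animal
    n_cycles: TrainingCycles
    outcome: Choice

Usage::

    python scripts/fit_source_data.py --input decisions.csv --out results/
    python scripts/fit_source_data.py --input source_data.xlsx \
        --column-map columns.yaml --phase post --out results/
"""

from __future__ import annotations

import argparse
import sys
import tempfile
from pathlib import Path

import pandas as pd
import yaml

from larvalearn.cli import PHASES
from larvalearn.data import TableDialect, read_decision_table
from larvalearn.models import compare_models, preference_table, untrained_fraction_curve


def parse_args(argv=None):
    ap = argparse.ArgumentParser(description=__doc__,
                                 formatter_class=argparse.RawDescriptionHelpFormatter)
    ap.add_argument("--input", required=True, help="CSV/TSV/XLSX per-decision table")
    ap.add_argument("--column-map", default=None,
                    help="YAML mapping semantic role -> spreadsheet column name")
    ap.add_argument("--sheet", default=0, help="Excel sheet name or index")
    ap.add_argument("--delimiter", default=",", help="Delimiter for text tables")
    ap.add_argument("--phase", default="post", choices=sorted(PHASES))
    ap.add_argument("--models",
                    default="all_or_none,quantized,graded,shifting_mean,three_cluster")
    ap.add_argument("--n-starts", type=int, default=20)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", required=True, help="Output directory")
    return ap.parse_args(argv)


def main(argv=None) -> int:
    args = parse_args(argv)
    columns = dict(TableDialect().columns)
    if args.column_map:
        columns.update(yaml.safe_load(Path(args.column_map).read_text()))
    dialect = TableDialect(delimiter=args.delimiter, columns=columns)

    path = Path(args.input)
    if path.suffix.lower() in (".xlsx", ".xls"):
        sheet = int(args.sheet) if str(args.sheet).isdigit() else args.sheet
        df = pd.read_excel(path, sheet_name=sheet)
        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
            df.to_csv(fh.name, index=False)
            groups = read_decision_table(fh.name, dialect)
    else:
        groups = read_decision_table(path, dialect)

    X = preference_table(groups, PHASES[args.phase])
    if X.empty:
        print("no larvae with decisions in the requested phase", file=sys.stderr)
        return 1
    names = [s.strip() for s in args.models.split(",") if s.strip()]
    table, fits = compare_models(X, names, n_starts=args.n_starts,
                                 random_state=args.seed)

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "model_comparison.csv", index=False)
    if "quantized" in fits:
        curve = untrained_fraction_curve(X, fits["quantized"], fits.get("all_or_none"))
        curve.to_csv(out / "untrained_fraction.csv", index=False)
    print(table.to_string(index=False))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
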