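#!/usr/bin/env python
"""Filter the alignment and classify its site patterns.

Reports how many positions survive the gap/missing/ambiguity filter and how
the retained columns split into constant, singleton-variable and
parsimony-informative sites — the figures that size the phylogenetic signal.
"""

import argparse
from pathlib import Path

from caridelim import seqio
from caridelim.sitestats import classify_sites

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fasta", type=Path, default=ROOT / "results" / "data" / "alignment.fasta")
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "align_stats")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    aln = seqio.read_alignment(args.fasta)
    filtered, report = seqio.filter_columns(aln)
    report.to_json(args.outdir / "filter_report.json")
    sc = classify_sites(filtered)
    sc.to_json(args.outdir / "site_classification.json")

    pct = 100.0 * sc.n_parsimony_informative / sc.n_variable if sc.n_variable else 0.0
    print(
        f"{report.n_input_columns} input columns, {report.n_excluded} excluded -> "
        f"{sc.n_total} aligned positions; {sc.n_variable} variable, of which "
        f"{sc.n_parsimony_informative} ({pct:.0f}%) parsimony-informative"
    )


if __name__ == "__main__":
    main()
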