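#!/usr/bin/env python
"""Download the study's 16S GenBank accessions and align them (network required).

Fetches the twenty 16S rDNA sequences (KF923712-KF923730 plus the outgroup
EU448997) from NCBI E-utilities and, if ``mafft`` is on PATH, writes a default
MAFFT alignment next to the raw download. Nothing in the test suite or the
acceptance script depends on this helper: the repository's analyses run on
synthetic data so they work fully offline.

Usage:
    python scripts/fetch_accessions.py --outdir data/real
"""

from __future__ import annotations

import argparse
import shutil
import subprocess
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = [f"KF9237{n:02d}" for n in range(12, 31)] + ["EU448997"]
EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={ids}&rettype=fasta&retmode=text"
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("data/real"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    url = EFETCH.format(ids=",".join(ACCESSIONS))
    raw = args.outdir / "16s_accessions.fasta"
    print(f"fetching {len(ACCESSIONS)} accessions from NCBI ...", file=sys.stderr)
    with urllib.request.urlopen(url, timeout=60) as resp:
        raw.write_bytes(resp.read())
    print(f"wrote {raw}", file=sys.stderr)

    if shutil.which("mafft"):
        aligned = args.outdir / "16s_aligned.fasta"
        with open(aligned, "w") as fh:
            subprocess.run(["mafft", "--auto", str(raw)], stdout=fh, check=True)
        print(f"wrote {aligned}", file=sys.stderr)
    else:
        print("mafft not found on PATH; align the raw FASTA yourself", file=sys.stderr)


if __name__ == "__main__":
    main()
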