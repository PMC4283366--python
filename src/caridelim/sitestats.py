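"""Site-pattern classification and pairwise divergence.

Distances are stored as *proportions* (a p-distance of 12.5% is 0.125);
conversion to percent happens only in reporting code. Corrected divergences
use the Jukes–Cantor (JC) one-parameter or Kimura two-parameter (K2P)
multiple-hit corrections:

    JC:  d = -(3/4) ln(1 - 4p/3)
    K2P: d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

with ``P`` and ``Q`` the transition and transversion proportions (P + Q = p).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .seqio import ACGT, AMBIGUOUS, GAP, MISSING, Alignment

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

DeletionMode = Literal["complete", "pairwise"]
Model = Literal["JC", "K2P"]


@dataclass(frozen=True)
class SiteClassification:
    """Counts of constant / variable / singleton / parsimony-informative columns."""

    n_total: int
    n_constant: int
    n_variable: int
    n_singleton: int
    n_parsimony_informative: int

    def __post_init__(self) -> None:
        if self.n_constant + self.n_variable != self.n_total:
            raise ValueError("constant + variable must equal total")
        if self.n_singleton + self.n_parsimony_informative != self.n_variable:
            raise ValueError("singleton + parsimony-informative must equal variable")
        if min(
            self.n_total,
            self.n_constant,
            self.n_variable,
            self.n_singleton,
            self.n_parsimony_informative,
        ) < 0:
            raise ValueError("site counts must be non-negative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labelled matrix of pairwise divergences (proportions or subs/site)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v[~np.isnan(v)] < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    def to_phylip(self, path: str | Path) -> None:
        """Square PHYLIP format (labels padded to 10 characters)."""
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            name = f"{lab[:10]:<10}"
            lines.append(name + " ".join(f"{x:.6f}" for x in row))
        Path(path).write_text("\n".join(lines) + "\n")


def _require_plain_acgt(aln: Alignment) -> None:
    for rec in aln.records:
        extra = set(rec.residues) - ACGT
        if extra:
            raise ValueError(
                f"sequence {rec.id!r} contains non-ACGT symbols {sorted(extra)}; "
                "run seqio.filter_columns first"
            )


def classify_sites(aln: Alignment) -> SiteClassification:
    """Classify each column of a filtered ACGT alignment.

    A column is *variable* iff at least two distinct states occur;
    *parsimony-informative* iff at least two states each occur in at least two
    sequences; variable-but-not-informative columns are *singleton* sites.
    """
    _require_plain_acgt(aln)
    constant = singleton = informative = 0
    for j in range(aln.length):
        counts: dict[str, int] = {}
        for r in aln.records:
            s = r.residues[j]
            counts[s] = counts.get(s, 0) + 1
        if len(counts) == 1:
            constant += 1
        elif sum(1 for c in counts.values() if c >= 2) >= 2:
            informative += 1
        else:
            singleton += 1
    return SiteClassification(
        n_total=aln.length,
        n_constant=constant,
        n_variable=singleton + informative,
        n_singleton=singleton,
        n_parsimony_informative=informative,
    )


_EXCLUDABLE = AMBIGUOUS | {GAP, MISSING}


def _comparable_mask(a: str, b: str) -> np.ndarray:
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    bad = np.array(sorted(_EXCLUDABLE), dtype="S1")
    return ~(np.isin(arr_a, bad) | np.isin(arr_b, bad))


def p_distance(aln: Alignment, deletion: DeletionMode = "complete") -> DistanceMatrix:
    """Uncorrected proportion of differing sites for every sequence pair.

    ``deletion="complete"`` requires a pre-filtered ACGT alignment and compares
    all columns; ``deletion="pairwise"`` skips, per pair, columns where either
    sequence carries a gap/missing/ambiguous symbol.
    """
    if len(aln) < 2:
        raise ValueError("p_distance requires at least two sequences")
    if deletion == "complete":
        _require_plain_acgt(aln)

    n = len(aln)
    seqs = [r.residues for r in aln.records]
    arrays = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if deletion == "pairwise":
                mask = _comparable_mask(seqs[i], seqs[j])
                n_comp = int(mask.sum())
                if n_comp == 0:
                    raise ValueError(
                        f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
                    )
                mism = int((arrays[i][mask] != arrays[j][mask]).sum())
            else:
                n_comp = aln.length
                mism = int((arrays[i] != arrays[j]).sum())
            values[i, j] = values[j, i] = mism / n_comp
    return DistanceMatrix(labels=tuple(aln.ids), values=values)


def transition_transversion_split(
    aln: Alignment, deletion: DeletionMode = "complete"
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Per-pair transition (P) and transversion (Q) proportions, P + Q = p."""
    if len(aln) < 2:
        raise ValueError("requires at least two sequences")
    if deletion == "complete":
        _require_plain_acgt(aln)
    n = len(aln)
    seqs = [r.residues for r in aln.records]
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ts = tv = comp = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in _EXCLUDABLE or b in _EXCLUDABLE:
                    if deletion == "pairwise":
                        continue
                    raise ValueError("unfiltered symbols under complete deletion")
                comp += 1
                if a == b:
                    continue
                same_class = (a in PURINES) == (b in PURINES)
                if same_class:
                    ts += 1
                else:
                    tv += 1
            if comp == 0:
                raise ValueError(
                    f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            P[i, j] = P[j, i] = ts / comp
            Q[i, j] = Q[j, i] = tv / comp
    labels = tuple(aln.ids)
    return DistanceMatrix(labels, P), DistanceMatrix(labels, Q)


def correct_distance(
    p: float,
    model: Model = "K2P",
    *,
    P: float | None = None,
    Q: float | None = None,
) -> float:
    """Convert an uncorrected proportion into model-corrected substitutions/site.

    For K2P, supply the transition proportion ``P`` and transversion proportion
    ``Q`` with ``P + Q = p``. Raises ``ValueError`` at or beyond the model's
    saturation bound (JC: p >= 0.75; K2P: 2P + Q >= 1 or 2Q >= 1).
    """
    if p < 0:
        raise ValueError("p-distance must be non-negative")
    if model == "JC":
        if p >= 0.75:
            raise ValueError(f"distance undefined under JC for p = {p}")
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    if model == "K2P":
        if P is None or Q is None:
            raise ValueError("K2P correction requires transition/transversion split")
        if not math.isclose(P + Q, p, abs_tol=1e-9):
            raise ValueError("K2P requires P + Q = p")
        if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
            raise ValueError(f"distance undefined under K2P for P = {P}, Q = {Q}")
        return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
    raise ValueError(f"unknown correction model {model!r}")


def corrected_matrix(
    aln: Alignment, model: Model = "K2P", deletion: DeletionMode = "complete"
) -> DistanceMatrix:
    """Model-corrected divergence for every pair of sequences."""
    pm = p_distance(aln, deletion)
    n = len(pm.labels)
    out = np.zeros((n, n))
    if model == "JC":
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = correct_distance(pm.values[i, j], "JC")
    else:
        Pm, Qm = transition_transversion_split(aln, deletion)
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = correct_distance(
                    pm.values[i, j], "K2P", P=Pm.values[i, j], Q=Qm.values[i, j]
                )
    return DistanceMatrix(pm.labels, out)


def jc_expected_p(d: float) -> float:
    """Expected p-distance after corrected divergence ``d`` under JC."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
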