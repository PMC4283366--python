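"""Block-wise diagnostic-character screening ("optimized comparison").

The screen looks for categorical morphological characters that separate two
molecularly delimited clades. It proceeds in three stages, each driven by the
same *constancy* statistic — the fraction of a clade's scored specimens showing
that clade's candidate (modal) state:

1. ``initial_screen``: on the molecular-voucher specimens only, list every
   character whose modal states differ between the clades with constancy
   strictly above the threshold (default 0.80) in *both* clades.
2. ``block_validate``: feed in the remaining specimens from the voucher lots in
   shuffled blocks (default 10 per clade per block); after each block the
   *cumulative* constancy is recomputed against the fixed modal states, and a
   character is discarded the first time either clade drops below threshold.
   Discarded characters are never revisited.
3. ``final_check``: repeat the cumulative block rule on hold-out specimens from
   lots with no molecular voucher.

Every decision is recorded in a :class:`ScreeningTrace` for audit.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN = "unknown"

_META_COLS = ["id", "lot", "clade", "stage", "voucher"]


@dataclass(frozen=True)
class Specimen:
    id: str
    lot: str
    clade: str
    stage: str  # "adult" | "juvenile"
    molecular_voucher: bool


@dataclass(frozen=True)
class CharacterMatrix:
    """Specimen x character grid of categorical state codes (or ``"unknown"``).

    State codes are opaque tokens; no ordering is assumed.
    """

    specimens: tuple[Specimen, ...]
    characters: tuple[str, ...]
    states: tuple[tuple[str, ...], ...]  # row per specimen

    def __post_init__(self) -> None:
        if len(self.states) != len(self.specimens):
            raise ValueError("state grid rows must match specimen count")
        for row in self.states:
            if len(row) != len(self.characters):
                raise ValueError("state grid columns must match character count")
        if len({s.clade for s in self.specimens}) < 2:
            raise ValueError("character matrix needs specimens from >= 2 clades")

    def state(self, specimen_idx: int, character: str) -> str:
        return self.states[specimen_idx][self.characters.index(character)]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CharacterMatrix":
        cols = [c.strip().lower() for c in df.columns]
        df = df.copy()
        df.columns = cols
        missing = [c for c in _META_COLS if c not in cols]
        if missing:
            raise ValueError(f"character matrix missing columns: {missing}")
        chars = [c for c in cols if c not in _META_COLS]
        specs = tuple(
            Specimen(
                id=str(r["id"]),
                lot=str(r["lot"]),
                clade=str(r["clade"]),
                stage=str(r["stage"]),
                molecular_voucher=str(r["voucher"]).strip().lower()
                in {"yes", "true", "1"},
            )
            for _, r in df.iterrows()
        )
        states = tuple(
            tuple(str(r[c]) if pd.notna(r[c]) and str(r[c]) != "" else UNKNOWN for c in chars)
            for _, r in df.iterrows()
        )
        return cls(specimens=specs, characters=tuple(chars), states=states)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CharacterMatrix":
        return cls.from_dataframe(pd.read_csv(path, dtype=str))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for spec, st in zip(self.specimens, self.states):
            rows.append(
                [spec.id, spec.lot, spec.clade, spec.stage,
                 "yes" if spec.molecular_voucher else "no", *st]
            )
        return pd.DataFrame(rows, columns=[*_META_COLS, *self.characters])

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class CandidateDiagnosis:
    """A character whose clade-modal states differ with high per-clade constancy.

    ``n_matched``/``n_scored`` are cumulative over every specimen the screen
    has consumed so far, so later stages can continue the running tally.
    """

    character: str
    modal_states: dict[str, str]  # clade -> modal state
    constancy: dict[str, float]  # clade -> fraction of known states matching modal
    n_scored: dict[str, int]  # clade -> specimens with known state
    n_matched: dict[str, int] = field(default_factory=dict)  # clade -> modal-state count


@dataclass
class BlockRecord:
    block_index: int
    character: str
    n_used: dict[str, int]  # specimens consumed this block, per clade
    cumulative_constancy: dict[str, float]
    decision: str  # "retained" | "discarded"


@dataclass
class ScreeningTrace:
    """Ordered audit of every screening decision plus warnings."""

    stage: str
    blocks: list[BlockRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stage": self.stage,
            "warnings": self.warnings,
            "blocks": [
                {
                    "block_index": b.block_index,
                    "character": b.character,
                    "n_used": b.n_used,
                    "cumulative_constancy": b.cumulative_constancy,
                    "decision": b.decision,
                }
                for b in self.blocks
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def to_table(self) -> pd.DataFrame:
        rows = [
            (b.block_index, b.character,
             json.dumps(b.n_used, sort_keys=True),
             json.dumps({k: round(v, 4) for k, v in b.cumulative_constancy.items()},
                        sort_keys=True),
             b.decision)
            for b in self.blocks
        ]
        return pd.DataFrame(
            rows, columns=["block", "character", "n_used", "cumulative_constancy", "decision"]
        )


def _eligible(m: CharacterMatrix, clade: str, adults_only: bool) -> list[int]:
    return [
        k
        for k, s in enumerate(m.specimens)
        if s.clade == clade and (not adults_only or s.stage == "adult")
    ]


def initial_screen(
    m: CharacterMatrix,
    clades: tuple[str, str],
    threshold: float = 0.80,
    adults_only: bool = True,
    trace: ScreeningTrace | None = None,
) -> list[CandidateDiagnosis]:
    """Stage 1: candidate characters from the molecular-voucher specimens.

    A character becomes a candidate iff its modal state differs between the two
    clades *and* the constancy (modal count / known count) is strictly greater
    than ``threshold`` in both clades. Modal-state ties within a clade make the
    character non-diagnosable for this comparison and it is skipped (recorded
    in the trace).
    """
    if trace is None:
        trace = ScreeningTrace(stage="initial")
    present = {s.clade for s in m.specimens}
    absent = [c for c in clades if c not in present]
    if absent:
        raise ValueError(f"clades absent from character matrix: {absent}")

    pools = {
        c: [k for k in _eligible(m, c, adults_only) if m.specimens[k].molecular_voucher]
        for c in clades
    }
    out: list[CandidateDiagnosis] = []
    for ci, char in enumerate(m.characters):
        modal: dict[str, str] = {}
        const: dict[str, float] = {}
        nsc: dict[str, int] = {}
        skip = False
        for clade in clades:
            known = [
                m.states[k][ci] for k in pools[clade] if m.states[k][ci] != UNKNOWN
            ]
            if not known:
                trace.warnings.append(
                    f"character {char!r}: no scored voucher specimens in clade {clade!r}; skipped"
                )
                skip = True
                break
            counts = Counter(known)
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                trace.warnings.append(
                    f"character {char!r}: modal-state tie in clade {clade!r}; skipped"
                )
                skip = True
                break
            modal[clade] = top[0][0]
            const[clade] = top[0][1] / len(known)
            nsc[clade] = len(known)
        if skip:
            continue
        if modal[clades[0]] == modal[clades[1]]:
            continue
        if all(const[c] > threshold for c in clades):
            out.append(
                CandidateDiagnosis(
                    character=char,
                    modal_states=modal,
                    constancy=const,
                    n_scored=nsc,
                    n_matched={c: round(const[c] * nsc[c]) for c in clades},
                )
            )
    return out


def _match_counts(
    m: CharacterMatrix, idxs: list[int], char_idx: int, modal_state: str
) -> tuple[int, int]:
    """(# specimens matching modal state, # with known state) over ``idxs``."""
    known = [k for k in idxs if m.states[k][char_idx] != UNKNOWN]
    match = sum(1 for k in known if m.states[k][char_idx] == modal_state)
    return match, len(known)


def _run_blocks(
    cands: list[CandidateDiagnosis],
    m: CharacterMatrix,
    clades: tuple[str, str],
    pools: dict[str, list[int]],
    block_size: int,
    threshold: float,
    seed: int,
    trace: ScreeningTrace,
) -> list[CandidateDiagnosis]:
    """Shared cumulative-constancy block loop for stages 2 and 3."""
    rng = np.random.default_rng(seed)
    shuffled = {c: list(rng.permutation(pools[c])) for c in clades}
    n_blocks = max(
        (len(shuffled[c]) + block_size - 1) // block_size for c in clades
    )
    # running (match, known) per character per clade, continued from the prior stage
    running = {
        cand.character: {
            c: (cand.n_matched.get(c, 0), cand.n_scored.get(c, 0)) for c in clades
        }
        for cand in cands
    }
    alive = list(cands)
    char_idx = {ch: m.characters.index(ch) for ch in m.characters}

    for b in range(n_blocks):
        block = {
            c: shuffled[c][b * block_size:(b + 1) * block_size] for c in clades
        }
        survivors: list[CandidateDiagnosis] = []
        for cand in alive:
            ci = char_idx[cand.character]
            cum: dict[str, float] = {}
            ok = True
            for clade in clades:
                dm, dk = _match_counts(m, block[clade], ci, cand.modal_states[clade])
                pm, pk = running[cand.character][clade]
                running[cand.character][clade] = (pm + dm, pk + dk)
                tot_m, tot_k = running[cand.character][clade]
                cum[clade] = tot_m / tot_k if tot_k else float("nan")
                if tot_k and cum[clade] < threshold:
                    ok = False
            decision = "retained" if ok else "discarded"
            trace.blocks.append(
                BlockRecord(
                    block_index=b + 1,
                    character=cand.character,
                    n_used={c: len(block[c]) for c in clades},
                    cumulative_constancy=cum,
                    decision=decision,
                )
            )
            if ok:
                survivors.append(cand)
        alive = survivors
        if not alive:
            break
    # update cumulative constancies on survivors
    out = []
    for cand in alive:
        const = {}
        nsc = {}
        nmt = {}
        for clade in clades:
            tot_m, tot_k = running[cand.character][clade]
            const[clade] = tot_m / tot_k if tot_k else float("nan")
            nsc[clade] = tot_k
            nmt[clade] = tot_m
        out.append(
            CandidateDiagnosis(
                character=cand.character,
                modal_states=cand.modal_states,
                constancy=const,
                n_scored=nsc,
                n_matched=nmt,
            )
        )
    return out


def block_validate(
    cands: list[CandidateDiagnosis],
    m: CharacterMatrix,
    clades: tuple[str, str],
    block_size: int = 10,
    threshold: float = 0.80,
    seed: int = 0,
    adults_only: bool = True,
) -> tuple[list[CandidateDiagnosis], ScreeningTrace]:
    """Stage 2: cumulative block validation on the remaining voucher-lot specimens.

    The validation pool is every eligible specimen from a lot that contains a
    molecular voucher, excluding the voucher specimens already used by
    ``initial_screen``. Blocks are drawn in a seed-determined shuffled order;
    the last block may be short. A character is discarded at the first block
    where either clade's cumulative constancy falls strictly below threshold.
    """
    trace = ScreeningTrace(stage="block-validate")
    voucher_lots = {s.lot for s in m.specimens if s.molecular_voucher}
    pools = {
        c: [
            k
            for k in _eligible(m, c, adults_only)
            if not m.specimens[k].molecular_voucher
            and m.specimens[k].lot in voucher_lots
        ]
        for c in clades
    }
    if all(not pools[c] for c in clades):
        trace.warnings.append("empty validation pool; candidates passed through unchanged")
        return list(cands), trace
    survivors = _run_blocks(
        cands, m, clades, pools, block_size, threshold, seed, trace
    )
    return survivors, trace


def final_check(
    survivors: list[CandidateDiagnosis],
    m: CharacterMatrix,
    clades: tuple[str, str],
    block_size: int = 10,
    threshold: float = 0.80,
    seed: int = 0,
    adults_only: bool = True,
) -> tuple[list[CandidateDiagnosis], ScreeningTrace]:
    """Stage 3: confirm survivors on hold-out lots containing no molecular voucher.

    The hold-out blocks continue the same cumulative step-by-step tally the
    survivors carry from the earlier stages ("additional blocks" of the one
    running evaluation), so a survivor is removed at the first hold-out block
    where either clade's cumulative constancy falls below threshold.
    """
    trace = ScreeningTrace(stage="final-check")
    voucher_lots = {s.lot for s in m.specimens if s.molecular_voucher}
    pools = {
        c: [
            k
            for k in _eligible(m, c, adults_only)
            if m.specimens[k].lot not in voucher_lots
        ]
        for c in clades
    }
    if all(not pools[c] for c in clades):
        trace.warnings.append("no hold-out lots; survivors confirmed without final check")
        return list(survivors), trace
    confirmed = _run_blocks(
        survivors, m, clades, pools, block_size, threshold, seed, trace
    )
    return confirmed, trace


def run_screen(
    m: CharacterMatrix,
    clades: tuple[str, str],
    threshold: float = 0.80,
    block_size: int = 10,
    adults_only: bool = True,
    seed: int = 0,
) -> tuple[list[CandidateDiagnosis], list[ScreeningTrace]]:
    """Full three-stage screen; returns confirmed diagnoses and all traces."""
    t0 = ScreeningTrace(stage="initial")
    cands = initial_screen(m, clades, threshold, adults_only, trace=t0)
    surv, t1 = block_validate(
        cands, m, clades, block_size, threshold, seed, adults_only
    )
    final, t2 = final_check(
        surv, m, clades, block_size, threshold, seed + 1, adults_only
    )
    return final, [t0, t1, t2]
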