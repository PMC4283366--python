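"""Clock-like sequence simulation and clade-structured morphology generation.

The default sequence scenario mirrors the study system: three ingroup lineages
("carteri" splitting from an "ivonicus"+"yuna" pair 10 Ma ago, the latter two
separating 2.6 Ma ago) plus a distant outgroup, evolving 435 sites under a
strict clock of 0.0083 substitutions/site/Myr. Within-lineage variation is
modelled as short terminal branches hanging off each lineage tip.

Substitutions are placed per branch as per-site Poisson counts with
multiple-hit overwriting, so the observed p-distance saturates exactly as the
Jukes–Cantor expectation E[p] = (3/4)(1 - e^(-8 r t / 3)) predicts for two
tips separated by total time 2t (the truth record stores these expectations
per pair for use as an oracle).
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .morphoscreen import CharacterMatrix, Specimen, UNKNOWN
from .seqio import Alignment, SequenceRecord

BASES = np.frombuffer(b"ACGT", dtype="S1")
_PURINE_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T transitions


@dataclass(frozen=True)
class LineageSpec:
    """One sampled lineage: its label and tip-ward structure."""

    label: str
    n_samples: int
    tip_depth_ma: float  # time each sample evolves independently below the lineage tip


@dataclass(frozen=True)
class ScenarioConfig:
    """Simulation scenario for clock-like 16S-style alignments.

    ``node_ages_ma`` fixes the ingroup topology
    ``((carteri, (ivonicus, yuna) @ t2) @ t1, outgroup @ t_root)``:
    t1 is the carteri vs ivonicus/yuna split, t2 the ivonicus vs yuna split
    and t_root the outgroup attachment. Rates are substitutions/site/Myr.
    """

    rate: float = 0.0083
    length: int = 435
    t1_ma: float = 10.0
    t2_ma: float = 2.6
    t_root_ma: float = 25.0
    model: str = "JC"  # "JC" or "K2P"
    kappa: float = 2.0  # transition/transversion rate ratio for K2P
    n_per_tip: int = 4
    tip_depth_ma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.t2_ma < self.t1_ma < self.t_root_ma):
            raise ValueError("node ages must increase root-ward: t2 < t1 < t_root")
        if self.rate < 0 or self.length <= 0:
            raise ValueError("rate must be >= 0 and length positive")
        if self.model not in {"JC", "K2P"}:
            raise ValueError(f"unknown simulation model {self.model!r}")


@dataclass(frozen=True)
class TruthRecord:
    """Generating parameters and closed-form expectations for a simulated alignment."""

    tree_newick: str
    rate: float
    split_times_ma: dict[str, float]
    pair_times_ma: dict[str, float]  # "id1|id2" -> time to MRCA (Ma)
    expected_p: dict[str, float]  # JC expectation per pair

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def jc_expected_p_for_split(rate: float, t_ma: float) -> float:
    """E[p] for two tips whose MRCA is ``t_ma`` Ma old under a JC clock."""
    return 0.75 * (1.0 - math.exp(-8.0 * rate * t_ma / 3.0))


def _evolve(seq: np.ndarray, rate: float, t_ma: float, model: str, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve a sequence along one branch; multiple hits overwrite each other."""
    out = seq.copy()
    if rate == 0 or t_ma == 0:
        return out
    n_hits = rng.poisson(rate * t_ma, size=seq.size)
    for site in np.nonzero(n_hits)[0]:
        state = int(out[site])
        for _ in range(int(n_hits[site])):
            if model == "JC":
                # uniform over the three alternatives
                state = (state + rng.integers(1, 4)) % 4
            else:
                # transition with probability kappa/(kappa+2), else one of the
                # two transversions
                if rng.random() < kappa / (kappa + 2.0):
                    state = _PURINE_PARTNER[state]
                else:
                    others = [s for s in range(4) if s != state and s != _PURINE_PARTNER[state]]
                    state = others[int(rng.integers(0, 2))]
        out[site] = state
    return out


def simulate_alignment(cfg: ScenarioConfig) -> tuple[Alignment, TruthRecord]:
    """Simulate a clock-like alignment on the default three-lineage-plus-outgroup tree.

    Returns the alignment (records labelled ``<lineage>_<k>`` carrying their
    lineage in the ``group`` metadata field) and a truth record with per-pair
    MRCA ages and JC expected p-distances. Fully reproducible from
    ``cfg.seed``. Emits a ``RuntimeWarning``-style warning entry if any
    root-to-tip path expects > 0.7 substitutions/site (saturation regime).
    """
    rng = np.random.default_rng(cfg.seed)
    L, r = cfg.length, cfg.rate
    if 2.0 * r * cfg.t_root_ma > 0.7:
        warnings.warn(
            "deepest tip-to-tip path expects "
            f"{2.0 * r * cfg.t_root_ma:.2f} substitutions/site (> 0.7): "
            "saturation regime",
            stacklevel=2,
        )

    if not cfg.tip_depth_ma < cfg.t2_ma:
        raise ValueError("tip_depth_ma must be smaller than the youngest split t2")

    root = rng.integers(0, 4, size=L)
    td = cfg.tip_depth_ma
    # node ages (Ma): root at t_root, ingroup split at t1, ivonicus/yuna split
    # at t2, each lineage's sample ancestor at tip_depth, samples at 0
    ingroup_anc = _evolve(root, r, cfg.t_root_ma - cfg.t1_ma, cfg.model, cfg.kappa, rng)
    carteri_tip = _evolve(ingroup_anc, r, cfg.t1_ma - td, cfg.model, cfg.kappa, rng)
    iy_anc = _evolve(ingroup_anc, r, cfg.t1_ma - cfg.t2_ma, cfg.model, cfg.kappa, rng)
    ivonicus_tip = _evolve(iy_anc, r, cfg.t2_ma - td, cfg.model, cfg.kappa, rng)
    yuna_tip = _evolve(iy_anc, r, cfg.t2_ma - td, cfg.model, cfg.kappa, rng)
    outgroup_tip = _evolve(root, r, cfg.t_root_ma, cfg.model, cfg.kappa, rng)

    tips = {
        "carteri": carteri_tip,
        "ivonicus": ivonicus_tip,
        "yuna": yuna_tip,
    }
    records: list[SequenceRecord] = []
    sample_group: dict[str, str] = {}
    for label, tip_seq in tips.items():
        for k in range(cfg.n_per_tip):
            s = _evolve(tip_seq, r, cfg.tip_depth_ma, cfg.model, cfg.kappa, rng)
            rid = f"{label}_{k + 1}"
            records.append(
                SequenceRecord(
                    id=rid,
                    residues=BASES[s].tobytes().decode(),
                    taxon=f"Palaemon {label}",
                    group="ivonicus_yuna" if label in ("ivonicus", "yuna") else label,
                )
            )
            sample_group[rid] = label
    records.append(
        SequenceRecord(
            id="outgroup_1",
            residues=BASES[outgroup_tip].tobytes().decode(),
            taxon="outgroup",
            group="outgroup",
        )
    )
    sample_group["outgroup_1"] = "outgroup"

    # time to MRCA for every sample pair
    def mrca_age(ga: str, gb: str) -> float:
        if ga == gb:
            return cfg.tip_depth_ma
        pair = {ga, gb}
        if "outgroup" in pair:
            return cfg.t_root_ma
        if pair == {"ivonicus", "yuna"}:
            return cfg.t2_ma
        return cfg.t1_ma

    pair_times: dict[str, float] = {}
    expected_p: dict[str, float] = {}
    ids = [rec.id for rec in records]
    for a, b in itertools.combinations(ids, 2):
        t = mrca_age(sample_group[a], sample_group[b])
        pair_times[f"{a}|{b}"] = t
        expected_p[f"{a}|{b}"] = jc_expected_p_for_split(r, t)

    newick = (
        f"((carteri:{cfg.t1_ma},(ivonicus:{cfg.t2_ma},"
        f"yuna:{cfg.t2_ma}):{cfg.t1_ma - cfg.t2_ma}):{cfg.t_root_ma - cfg.t1_ma},"
        f"outgroup:{cfg.t_root_ma});"
    )
    truth = TruthRecord(
        tree_newick=newick,
        rate=r,
        split_times_ma={"t1": cfg.t1_ma, "t2": cfg.t2_ma, "t_root": cfg.t_root_ma},
        pair_times_ma=pair_times,
        expected_p=expected_p,
    )
    return Alignment(tuple(records)), truth


@dataclass(frozen=True)
class CharacterSpec:
    """One simulated character: its diagnostic behaviour and noise level.

    ``kind``: "diagnostic" (clade-specific modal states, drawn with probability
    ``constancy``), "overlapping" (identical state distribution in all clades)
    or "ontogenetic" (diagnostic in adults; juveniles flip toward the other
    clade's state with probability ``juvenile_flip``).
    """

    name: str
    kind: str
    constancy: float = 0.95
    states: tuple[str, ...] = ("s0", "s1", "s2")
    juvenile_flip: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in {"diagnostic", "overlapping", "ontogenetic"}:
            raise ValueError(f"unknown character kind {self.kind!r}")
        if self.kind != "overlapping" and not (0.5 < self.constancy <= 1.0):
            raise ValueError("diagnostic constancy must lie in (0.5, 1]")


@dataclass(frozen=True)
class MorphScenario:
    """Scenario for a clade-structured categorical morphology matrix."""

    n_per_clade: int = 80
    n_lots_per_clade: int = 8
    characters: tuple[CharacterSpec, ...] = (
        CharacterSpec("antennular_projection", "diagnostic", 0.95),
        CharacterSpec("anterolateral_spine", "diagnostic", 0.90),
        CharacterSpec("rostrum_teeth", "overlapping"),
        CharacterSpec("appendix_masculina", "ontogenetic", 0.95),
    )
    juvenile_fraction: float = 0.15
    voucher_fraction: float = 0.5
    unknown_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.juvenile_fraction, self.voucher_fraction, self.unknown_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_per_clade < 2:
            raise ValueError("need at least 2 specimens per clade")


def simulate_morphology(
    ms: MorphScenario, clades: tuple[str, str] = ("carteri", "ivonicus_yuna")
) -> tuple[CharacterMatrix, dict]:
    """Generate a specimen x character matrix with known diagnostic structure.

    Per clade: ``n_per_clade`` specimens spread round-robin over
    ``n_lots_per_clade`` lots; one lot per clade is reserved as hold-out (no
    molecular vouchers assigned to it); a ``voucher_fraction`` of the remaining
    specimens are flagged as molecular vouchers. Diagnostic characters draw the
    clade's modal state with probability ``constancy`` and a uniform
    alternative otherwise; overlapping characters draw from one shared
    distribution in both clades; ontogenetic characters behave diagnostically
    in adults while juveniles flip to the other clade's modal state with
    probability ``juvenile_flip``.

    Returns the matrix and a truth dict mapping character name to its spec.
    """
    rng = np.random.default_rng(ms.seed)
    specimens: list[Specimen] = []
    rows: list[tuple[str, ...]] = []
    modal = {
        spec.name: {clades[0]: spec.states[0], clades[1]: spec.states[1]}
        for spec in ms.characters
    }

    for clade in clades:
        lots = [f"{clade}_lot{j + 1}" for j in range(ms.n_lots_per_clade)]
        holdout_lot = lots[-1] if ms.n_lots_per_clade > 1 else None
        for i in range(ms.n_per_clade):
            lot = lots[i % ms.n_lots_per_clade]
            juvenile = rng.random() < ms.juvenile_fraction
            voucher = (
                lot != holdout_lot
                and not juvenile
                and rng.random() < ms.voucher_fraction
            )
            specimens.append(
                Specimen(
                    id=f"{clade}_{i + 1}",
                    lot=lot,
                    clade=clade,
                    stage="juvenile" if juvenile else "adult",
                    molecular_voucher=voucher,
                )
            )
    # guarantee at least two adult vouchers per clade in a non-holdout lot
    for clade in clades:
        have = [
            k for k, s in enumerate(specimens)
            if s.clade == clade and s.molecular_voucher
        ]
        need = 2 - len(have)
        if need > 0:
            candidates = [
                k for k, s in enumerate(specimens)
                if s.clade == clade and s.stage == "adult"
                and not s.molecular_voucher
                and not s.lot.endswith(f"lot{ms.n_lots_per_clade}")
            ]
            for k in candidates[:need]:
                s = specimens[k]
                specimens[k] = Specimen(s.id, s.lot, s.clade, s.stage, True)

    other = {clades[0]: clades[1], clades[1]: clades[0]}
    for s in specimens:
        row: list[str] = []
        for spec in ms.characters:
            if rng.random() < ms.unknown_fraction:
                row.append(UNKNOWN)
                continue
            if spec.kind == "overlapping":
                # one shared distribution: clade-independent
                row.append(spec.states[int(rng.integers(0, len(spec.states)))])
                continue
            own = modal[spec.name][s.clade]
            alt_states = [st for st in spec.states if st != own]
            if rng.random() < spec.constancy:
                state = own
            else:
                state = alt_states[int(rng.integers(0, len(alt_states)))]
            if (
                spec.kind == "ontogenetic"
                and s.stage == "juvenile"
                and rng.random() < spec.juvenile_flip
            ):
                state = modal[spec.name][other[s.clade]]
            row.append(state)
        rows.append(tuple(row))

    matrix = CharacterMatrix(
        specimens=tuple(specimens),
        characters=tuple(spec.name for spec in ms.characters),
        states=tuple(rows),
    )
    truth = {
        spec.name: {
            "kind": spec.kind,
            "constancy": spec.constancy,
            "modal_states": modal[spec.name],
        }
        for spec in ms.characters
    }
    return matrix, truth
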