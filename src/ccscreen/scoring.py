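"""bCIPA-style quantitative scoring of coiled-coil pairs.

The predicted melting temperature of a parallel dimeric coiled coil is a
linear function of three sequence-derived terms::

    Tm = w_hp * HP + w_cs * CS + w_es * ES + intercept

where CS is the summed core coupling free energy over the a-a' pairs, ES the
summed electrostatic coupling free energy over the g-e'/e-g' pairs (both in
kcal/mol, from double-mutant-cycle derived tables) and HP the helical
propensity of the component chains (here the mean per-residue propensity
over the scored residues of both chains).

The shipped pairing-energy tables are the double-mutant-analysis values for
the Asn/Ile core and Glu/Lys electrostatic options used throughout this
design family:

==========  ==========  =================
contact     pair        kcal/mol
==========  ==========  =================
core a-a'   Ile-Ile     -9.2
core a-a'   Asn-Asn     -2.4
core a-a'   Asn-Ile     -0.5
g-e'/e-g'   Glu-Lys     -1.2
g-e'/e-g'   Glu-Glu     +0.4
g-e'/e-g'   Lys-Lys     -0.3
==========  ==========  =================

The regression coefficients of the published bCIPA fit are not bundled: the
model is a pluggable named coefficient set, and the default
(``demo-linear``) is a placeholder with physically sensible signs chosen so
that the shipped demonstration configuration preserves the qualitative
ordering desired pair >> off-target >> repulsive homodimer.  All free-energy
decompositions are independent of the coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .heptad import (
    CAP,
    STANDARD_AA,
    RegisteredPeptide,
    antiparallel_electrostatic_pairs,
    parallel_core_pairs,
    parallel_electrostatic_pairs,
)

__all__ = [
    "PairScoreTable",
    "HelicityTable",
    "TmModel",
    "PairScore",
    "ScoreTableError",
    "DEFAULT_PAIR_SCORES",
    "DEFAULT_HELICITY",
    "DEFAULT_TM_MODEL",
    "delta_g_core",
    "delta_g_electrostatic",
    "helicity_score",
    "predict_tm",
    "score_pair",
]


class ScoreTableError(KeyError):
    """A residue pair (or residue) is absent from a score table."""


def _key(r1: str, r2: str) -> tuple[str, str]:
    return (r1, r2) if r1 <= r2 else (r2, r1)


@dataclass(frozen=True)
class PairScoreTable:
    """Unordered residue-pair free energies for core and electrostatic contacts.

    ``default_missing`` is the policy for pairs absent from a table:
    ``"error"`` (default; catches register mistakes early) or ``"zero"``
    (permissive mode for exploratory libraries with residues outside the
    tabulated options).
    """

    core: Mapping[tuple[str, str], float]
    electro: Mapping[tuple[str, str], float]
    default_missing: str = "error"

    def __post_init__(self) -> None:
        if self.default_missing not in ("error", "zero"):
            raise ValueError("default_missing must be 'error' or 'zero'")
        object.__setattr__(self, "core", {_key(*k): v for k, v in self.core.items()})
        object.__setattr__(self, "electro", {_key(*k): v for k, v in self.electro.items()})

    def _lookup(self, table: Mapping[tuple[str, str], float], r1: str, r2: str, what: str) -> float:
        try:
            return table[_key(r1, r2)]
        except KeyError:
            if self.default_missing == "zero":
                return 0.0
            raise ScoreTableError(
                f"no {what} score for residue pair {r1}-{r2}"
            ) from None

    def core_score(self, r1: str, r2: str) -> float:
        return self._lookup(self.core, r1, r2, "core")

    def electro_score(self, r1: str, r2: str) -> float:
        return self._lookup(self.electro, r1, r2, "electrostatic")


DEFAULT_PAIR_SCORES = PairScoreTable(
    core={("I", "I"): -9.2, ("N", "N"): -2.4, ("I", "N"): -0.5},
    electro={("E", "K"): -1.2, ("E", "E"): 0.4, ("K", "K"): -0.3},
)


class HelicityTable:
    """Per-residue helical-propensity values with per-chain caching.

    The pair-level score is the mean propensity over the scored (non-cap)
    residues of both chains, which keeps it length-independent.  Single-chain
    means are memoised on the scored sequence, so each peptide's value is
    computed once however many pairs it enters.
    """

    def __init__(self, values: Mapping[str, float], name: str = "custom") -> None:
        missing = STANDARD_AA - set(values)
        if missing:
            raise ValueError(f"helicity table lacks residue(s) {sorted(missing)}")
        for r, v in values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite helicity value for {r}")
        self.values = dict(values)
        self.name = name
        self._chain_cache: dict[str, float] = {}

    def residue(self, r: str) -> float:
        try:
            return self.values[r]
        except KeyError:
            raise ScoreTableError(f"no helicity value for residue {r!r}") from None

    def chain_mean(self, p: RegisteredPeptide) -> float:
        seq = p.scored_sequence()
        try:
            return self._chain_cache[seq]
        except KeyError:
            v = sum(self.residue(r) for r in seq) / len(seq)
            self._chain_cache[seq] = v
            return v


#: Helix propensities (kcal/mol relative to Ala) from the Pace & Scholtz
#: consensus scale.  Lower = more helix-favouring.  A public stand-in for
#: per-residue helicity; swap in any 20-residue table via configuration.
PACE_SCHOLTZ = {
    "A": 0.00, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26,
    "Q": 0.39, "E": 0.40, "I": 0.41, "W": 0.49, "S": 0.50,
    "Y": 0.53, "F": 0.54, "H": 0.61, "V": 0.61, "N": 0.65,
    "T": 0.66, "C": 0.68, "D": 0.69, "G": 1.00, "P": 3.16,
}

DEFAULT_HELICITY = HelicityTable(PACE_SCHOLTZ, name="pace-scholtz")


@dataclass
class TmModel:
    """Linear predicted-Tm model: coefficients + the tables they act on."""

    w_hp: float
    w_cs: float
    w_es: float
    intercept: float
    helicity: HelicityTable
    scores: PairScoreTable
    name: str = "custom"

    def __post_init__(self) -> None:
        for label, v in (("w_hp", self.w_hp), ("w_cs", self.w_cs),
                         ("w_es", self.w_es), ("intercept", self.intercept)):
            if v is None or not math.isfinite(v):
                raise ValueError(f"TmModel coefficient {label} is missing or non-finite")


def default_tm_model() -> TmModel:
    """The shipped ``demo-linear`` placeholder coefficient set.

    Signs are physical (more negative coupling energy and higher helicity
    raise the predicted Tm on the Pace-Scholtz cost scale); magnitudes are a
    documented placeholder chosen once so that the shipped demonstration
    configuration is internally coherent — fully complementary desired
    pairs clear the default 70 degC candidate floor while every Glu/Lys
    homodimer falls below the default 10 degC import cutoff.  It is not the
    published regression fit, which must be transcribed into configuration
    before absolute predicted-Tm values can be compared with published
    screens.
    """
    return TmModel(
        w_hp=-20.0,
        w_cs=-1.0,
        w_es=-9.0,
        intercept=-32.0,
        helicity=DEFAULT_HELICITY,
        scores=DEFAULT_PAIR_SCORES,
        name="demo-linear",
    )


DEFAULT_TM_MODEL = default_tm_model()


@dataclass(frozen=True)
class PairScore:
    """Full score report for one unordered peptide pair."""

    idA: str
    idB: str
    tm_pred: float | None
    dg_core: float
    dg_electro: float
    hp: float
    orientation: str = "parallel"


def delta_g_core(
    pA: RegisteredPeptide,
    pB: RegisteredPeptide,
    table: PairScoreTable = DEFAULT_PAIR_SCORES,
) -> float:
    """Summed a-a' coupling free energy (kcal/mol) of the parallel dimer."""
    return sum(table.core_score(p.resA, p.resB) for p in parallel_core_pairs(pA, pB))


def delta_g_electrostatic(
    pA: RegisteredPeptide,
    pB: RegisteredPeptide,
    table: PairScoreTable = DEFAULT_PAIR_SCORES,
    orientation: str = "parallel",
) -> float:
    """Summed flanking-contact free energy (kcal/mol) for either geometry."""
    if orientation == "parallel":
        pairs = parallel_electrostatic_pairs(pA, pB)
    elif orientation == "antiparallel":
        pairs = antiparallel_electrostatic_pairs(pA, pB)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return sum(table.electro_score(p.resA, p.resB) for p in pairs)


def helicity_score(
    pA: RegisteredPeptide,
    pB: RegisteredPeptide,
    helicity_table: HelicityTable = DEFAULT_HELICITY,
) -> float:
    """Mean per-residue propensity over the scored residues of both chains."""
    sA, sB = pA.scored_sequence(), pB.scored_sequence()
    nA, nB = len(sA), len(sB)
    return (helicity_table.chain_mean(pA) * nA + helicity_table.chain_mean(pB) * nB) / (nA + nB)


def predict_tm(
    pA: RegisteredPeptide,
    pB: RegisteredPeptide,
    model: TmModel = DEFAULT_TM_MODEL,
) -> float:
    """Predicted melting temperature (deg C) of the parallel dimer.

    Symmetric in its two arguments; only the parallel geometry is the
    model's fitted domain.
    """
    cs = delta_g_core(pA, pB, model.scores)
    es = delta_g_electrostatic(pA, pB, model.scores, "parallel")
    hp = helicity_score(pA, pB, model.helicity)
    return model.w_hp * hp + model.w_cs * cs + model.w_es * es + model.intercept


def score_pair(
    pA: RegisteredPeptide,
    pB: RegisteredPeptide,
    model: TmModel = DEFAULT_TM_MODEL,
    orientation: str = "parallel",
) -> PairScore:
    """Full decomposition for one pair; Tm is reported only for parallel.

    In the antiparallel geometry the buried contacts are a-d', which carry
    no specificity signal with Leu fixed at d; the core term is therefore
    excluded (zero) for antiparallel scores.
    """
    cs = delta_g_core(pA, pB, model.scores) if orientation == "parallel" else 0.0
    es = delta_g_electrostatic(pA, pB, model.scores, orientation)
    hp = helicity_score(pA, pB, model.helicity)
    tm = (
        model.w_hp * hp + model.w_cs * cs + model.w_es * es + model.intercept
        if orientation == "parallel"
        else None
    )
    return PairScore(pA.id, pB.id, tm, cs, es, hp, orientation)
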