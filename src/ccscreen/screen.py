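"""Interactome screen: import filters, exhaustive pairwise Tm, storage policy.

The screen evaluates every unordered pair (homodimers included) among the
admitted peptides exactly once — N peptides give N(N+1)/2 evaluations — and
persists to the interaction store only pairs whose predicted Tm reaches the
desired-pair floor, which keeps the store tiny even for million-pair
interactomes while the full matrix remains exportable on demand.

Two import-time filters discard peptides that can never contribute a
specific pair: a homodimer-stability cutoff (predicted homodimer Tm above a
threshold) and, optionally, an antiparallel filter that removes peptides
whose antiparallel homodimer makes a fully charge-complementary set of
g-g'/e-e' contacts — such chains gain unmodelled stability in the
antiparallel geometry and defeat the parallel-only Tm model.

When every peptide shares one register layout (the normal case for a
template-derived library) the pairwise Tm matrix is computed with
vectorised table lookups; mixed layouts fall back to a per-pair loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .heptad import RegisteredPeptide, antiparallel_electrostatic_pairs
from .scoring import (
    DEFAULT_TM_MODEL,
    ScoreTableError,
    TmModel,
    helicity_score,
    predict_tm,
)

__all__ = [
    "ScreenCriteria",
    "Rejection",
    "Interactome",
    "import_filter",
    "screen_interactome",
    "write_store",
    "read_store",
]

logger = logging.getLogger(__name__)

#: Residue charge signs used by the antiparallel complementarity filter.
RESIDUE_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}

_FLOAT_FMT = "%.17g"  # lossless float round-trip in text exports


@dataclass(frozen=True)
class ScreenCriteria:
    """Tm thresholds (deg C) controlling the screen and the set search."""

    max_homodimer_tm: float = 10.0
    min_desired_tm: float = 70.0
    max_offtarget_tm_pairs: float = 20.0
    min_delta_tm_pairs: float = 50.0
    max_offtarget_tm_quads: float = 30.0
    min_delta_tm_quads: float = 40.0
    antiparallel_filter: bool = False

    def __post_init__(self) -> None:
        vals = (
            self.max_homodimer_tm, self.min_desired_tm,
            self.max_offtarget_tm_pairs, self.min_delta_tm_pairs,
            self.max_offtarget_tm_quads, self.min_delta_tm_quads,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all criteria thresholds must be finite")
        if not self.min_desired_tm > self.max_offtarget_tm_pairs:
            raise ValueError("min_desired_tm must exceed max_offtarget_tm_pairs")


@dataclass(frozen=True)
class Rejection:
    peptide_id: str
    reason: str  # "homodimer_tm" | "antiparallel_complementary"
    detail: float | None = None


def _antiparallel_fully_complementary(p: RegisteredPeptide) -> bool:
    """True if every antiparallel g-g'/e-e' homodimer contact is attractive.

    Attraction is judged by charge sign (acid against base); a peptide with
    no complete electrostatic heptad is never "fully complementary".
    """
    pairs = antiparallel_electrostatic_pairs(p, p)
    if not pairs:
        return False
    return all(
        RESIDUE_CHARGE.get(pr.resA, 0) * RESIDUE_CHARGE.get(pr.resB, 0) < 0
        for pr in pairs
    )


def import_filter(
    peptides: Iterable[RegisteredPeptide],
    model: TmModel = DEFAULT_TM_MODEL,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> tuple[list[RegisteredPeptide], list[Rejection]]:
    """Apply the import-time filters; returns (retained, rejection log).

    Peptides are dropped at the earliest opportunity — before any cross
    evaluation — when their parallel homodimer Tm exceeds
    ``criteria.max_homodimer_tm`` or (if ``criteria.antiparallel_filter``)
    when their antiparallel homodimer is fully electrostatically
    complementary.  Each peptide's helicity is computed here once and
    memoised for the whole screen.
    """
    retained: list[RegisteredPeptide] = []
    rejections: list[Rejection] = []
    for p in peptides:
        model.helicity.chain_mean(p)  # warm the cache
        homo_tm = predict_tm(p, p, model)
        if homo_tm > criteria.max_homodimer_tm:
            rejections.append(Rejection(p.id, "homodimer_tm", homo_tm))
            continue
        if criteria.antiparallel_filter and _antiparallel_fully_complementary(p):
            rejections.append(Rejection(p.id, "antiparallel_complementary"))
            continue
        retained.append(p)
    logger.info(
        "import filter: %d retained, %d rejected",
        len(retained), len(rejections),
    )
    return retained, rejections


class Interactome:
    """All-against-all predicted Tm over a set of admitted peptides.

    Holds the N×N symmetric Tm matrix plus provenance (model name and
    criteria).  The long table and the store view enumerate each unordered
    pair once, canonically ordered (idA <= idB lexicographically, rows
    sorted), so identical inputs give byte-identical exports.
    """

    def __init__(
        self,
        peptides: Sequence[RegisteredPeptide],
        tm_matrix: np.ndarray,
        model: TmModel,
        criteria: ScreenCriteria,
    ) -> None:
        self.peptides = list(peptides)
        self.tm_matrix = tm_matrix
        self.model = model
        self.criteria = criteria
        self._index = {p.id: i for i, p in enumerate(self.peptides)}

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def n_pairs(self) -> int:
        """Number of evaluated unordered pairs, N(N+1)/2."""
        n = len(self.peptides)
        return n * (n + 1) // 2

    def tm(self, idA: str, idB: str) -> float:
        """Predicted Tm for one unordered pair (homodimers allowed)."""
        return float(self.tm_matrix[self._index[idA], self._index[idB]])

    def long_table(self) -> pd.DataFrame:
        """One row per unordered pair: idA, idB, tm, stored flag."""
        rows = []
        ids = self.ids
        thr = self.criteria.min_desired_tm
        for i in range(len(ids)):
            for j in range(i, len(ids)):
                a, b = sorted((ids[i], ids[j]))
                tm = float(self.tm_matrix[i, j])
                rows.append((a, b, tm, tm >= thr))
        df = pd.DataFrame(rows, columns=["idA", "idB", "tm", "stored"])
        return df.sort_values(["idA", "idB"], ignore_index=True)

    def stored_interactions(self) -> pd.DataFrame:
        """The persisted subset: pairs with tm >= min_desired_tm."""
        df = self.long_table()
        return df.loc[df["stored"], ["idA", "idB", "tm"]].reset_index(drop=True)

    def matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tm_matrix, index=self.ids, columns=self.ids)

    def export_heatmap(
        self,
        matrix_path: str | Path,
        long_path: str | Path | None = None,
        image_path: str | Path | None = None,
    ) -> None:
        """Write the symmetric N×N Tm matrix as TSV (plus optional extras).

        The TSV round-trips bit-exactly (floats printed with 17 significant
        digits).  ``image_path`` renders a raster heatmap if matplotlib is
        available.
        """
        self.matrix_frame().to_csv(matrix_path, sep="\t", float_format=_FLOAT_FMT)
        if long_path is not None:
            self.long_table().to_csv(
                long_path, sep="\t", index=False, float_format=_FLOAT_FMT
            )
        if image_path is not None:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(6, 5))
            im = ax.imshow(self.tm_matrix, cmap="viridis")
            fig.colorbar(im, ax=ax, label="predicted Tm (deg C)")
            ax.set_title(f"{len(self.peptides)}-peptide interactome")
            fig.savefig(image_path, dpi=150)
            plt.close(fig)


def _encode(peptides: Sequence[RegisteredPeptide], indices) -> np.ndarray:
    aa_index = {aa: i for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}
    return np.array(
        [[aa_index[p.sequence[i]] for i in indices] for p in peptides], dtype=np.intp
    )


def _table_matrix(table, which: str, policy: str) -> np.ndarray:
    m = np.full((20, 20), np.nan)
    aa_index = {aa: i for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}
    src = table.core if which == "core" else table.electro
    for (r1, r2), v in src.items():
        m[aa_index[r1], aa_index[r2]] = v
        m[aa_index[r2], aa_index[r1]] = v
    if policy == "zero":
        m = np.nan_to_num(m)
    return m


def _tm_matrix_vectorised(
    peptides: Sequence[RegisteredPeptide], model: TmModel
) -> np.ndarray:
    """Full N×N predicted-Tm matrix via per-contact table-lookup broadcasts."""
    first = peptides[0]
    a_pos = first.positions("a")
    heptads = first.electro_heptads()
    policy = model.scores.default_missing
    core_m = _table_matrix(model.scores, "core", policy)
    electro_m = _table_matrix(model.scores, "electro", policy)

    a_idx = _encode(peptides, a_pos)
    g_idx = _encode(peptides, [g for g, _ in heptads])
    e_idx = _encode(peptides, [e for _, e in heptads])

    n = len(peptides)
    cs = np.zeros((n, n))
    for k in range(len(a_pos)):
        cs += core_m[a_idx[:, k][:, None], a_idx[None, :, k]]
    es = np.zeros((n, n))
    for k in range(len(heptads)):
        es += electro_m[g_idx[:, k][:, None], e_idx[None, :, k]]
        es += electro_m[e_idx[:, k][:, None], g_idx[None, :, k]]
    if policy == "error" and (np.isnan(cs).any() or np.isnan(es).any()):
        raise ScoreTableError(
            "score table lacks an entry for a residue pair in this library"
        )
    hp = np.array([model.helicity.chain_mean(p) for p in peptides])
    hp_mat = (hp[:, None] + hp[None, :]) / 2.0
    return model.w_hp * hp_mat + model.w_cs * cs + model.w_es * es + model.intercept


def screen_interactome(
    peptides: Sequence[RegisteredPeptide],
    model: TmModel = DEFAULT_TM_MODEL,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> Interactome:
    """Evaluate all N(N+1)/2 unordered pairs of the admitted peptides.

    Callers wanting the import-time filters apply :func:`import_filter`
    first; the screen itself never drops peptides.  Raises on duplicate
    peptide ids.
    """
    peptides = list(peptides)
    ids = [p.id for p in peptides]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate peptide id(s): {dupes}")
    n = len(peptides)
    if n == 0:
        return Interactome([], np.zeros((0, 0)), model, criteria)
    registers = {p.register for p in peptides}
    if len(registers) == 1:
        tm = _tm_matrix_vectorised(peptides, model)
        # exact symmetry: averaging removes float association noise
        tm = (tm + tm.T) / 2.0
    else:
        logger.info("mixed register layouts: falling back to per-pair loop")
        tm = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                tm[i, j] = tm[j, i] = predict_tm(peptides[i], peptides[j], model)
    logger.info("screened %d peptides: %d unordered pairs", n, n * (n + 1) // 2)
    return Interactome(peptides, tm, model, criteria)


def write_store(interactions: pd.DataFrame, path: str | Path) -> None:
    """Persist the super-threshold interaction table as a TSV store."""
    interactions.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_store(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"idA": str, "idB": str}, float_precision="round_trip"
    )
    expected = {"idA", "idB", "tm"}
    if not expected.issubset(df.columns):
        raise ValueError(f"interaction store {path} lacks columns {expected}")
    return df
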