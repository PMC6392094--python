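"""Isotopologue enrichment analysis: MDV, fractional contribution, pool sizes.

An LC-MS isotopologue measurement for a metabolite with ``c`` carbon atoms is a
vector of ion counts ``IC(M+i)`` for ``i = 0..c``, where ``i`` is the number of
heavy (13C) carbons.  Two summaries are computed from it:

* the mass distribution vector (MDV), the fractional abundance of each
  isotopologue relative to the total ion count (TIC);
* the fractional contribution (FC), the fraction of the metabolite's carbon
  atoms that are isotopically labeled — the ratio of relative labeled carbon
  (RLC) to relative total carbon (RTC)::

      MDV_i = IC(M+i) / sum_i IC(M+i)
      FC    = sum_{i>=1} i * IC(M+i)  /  ( c * sum_i IC(M+i) )

Per-cell pool sizes ("relative abundance") are TIC normalized to cell density.
Values are reported without 13C natural-abundance correction by default;
:func:`correct_natural_abundance` deconvolves the ~1.07 % background when asked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IsotopologueVector",
    "EnrichmentResult",
    "PoolMeasurement",
    "ReplicateSummary",
    "UndefinedEnrichmentError",
    "compute_mdv",
    "compute_fc",
    "natural_abundance_vector",
    "natural_abundance_matrix",
    "correct_natural_abundance",
    "normalize_per_cell",
    "summarize_replicates",
    "enrich_table",
    "NATURAL_13C_ABUNDANCE",
]

#: Standard terrestrial fractional abundance of 13C.
NATURAL_13C_ABUNDANCE = 0.0107


class UndefinedEnrichmentError(ValueError):
    """Raised when TIC = 0: the metabolite was not detected and MDV/FC are undefined."""


@dataclass(frozen=True)
class IsotopologueVector:
    """Raw ion counts for one metabolite in one sample.

    Parameters
    ----------
    metabolite : str
        Metabolite name.
    c : int
        Number of carbon atoms in the backbone (>= 1).
    counts : sequence of float
        Ion counts ``IC(M+i)`` for ``i = 0..c``; length must be ``c + 1``.
    time_min : float, optional
        Sampling time in minutes.
    biological_replicate, technical_replicate : str or int, optional
        Replicate identifiers.
    """

    metabolite: str
    c: int
    counts: tuple
    time_min: float | None = None
    biological_replicate: object = None
    technical_replicate: object = None

    def __post_init__(self):
        if self.c < 1:
            raise ValueError(f"carbon count must be >= 1, got {self.c}")
        counts = tuple(float(x) for x in self.counts)
        if len(counts) != self.c + 1:
            raise ValueError(
                f"{self.metabolite}: expected {self.c + 1} isotopologue counts "
                f"(i = 0..{self.c}), got {len(counts)}"
            )
        if any(x < 0 for x in counts):
            raise ValueError(f"{self.metabolite}: negative ion counts")
        object.__setattr__(self, "counts", counts)

    @property
    def tic(self) -> float:
        """Total ion count (sum over isotopologues)."""
        return float(sum(self.counts))


@dataclass(frozen=True)
class EnrichmentResult:
    """MDV and FC for one isotopologue vector, with RLC/RTC intermediates."""

    metabolite: str
    mdv: tuple
    fc: float
    rlc: float
    rtc: float
    time_min: float | None = None
    biological_replicate: object = None
    technical_replicate: object = None


@dataclass(frozen=True)
class PoolMeasurement:
    """Per-cell relative abundance: TIC normalized to cell density."""

    metabolite: str
    tic: float
    cell_density: float
    relative_abundance: float


@dataclass(frozen=True)
class ReplicateSummary:
    """Replicate roll-up: MDV averaged over technical replicates within each
    biological replicate; FC mean and SD across biological replicates."""

    metabolite: str
    mdv_by_biological: Mapping[object, tuple]
    fc_by_biological: Mapping[object, float]
    fc_mean: float
    fc_sd: float
    n_biological: int
    single_replicate: bool


def compute_mdv(v: IsotopologueVector) -> np.ndarray:
    """Mass distribution vector: fractional abundance of each isotopologue.

    Raises
    ------
    UndefinedEnrichmentError
        If all counts are zero (metabolite not detected).
    """
    counts = np.asarray(v.counts, dtype=float)
    tic = counts.sum()
    if tic <= 0.0:
        raise UndefinedEnrichmentError(
            f"{v.metabolite}: TIC = 0, enrichment undefined (not detected)"
        )
    return counts / tic


def compute_fc(v: IsotopologueVector) -> float:
    """Fractional contribution: RLC / RTC.

    RLC = sum_i IC(M+i) * i, RTC = c * TIC.  Invariant under uniform scaling
    of the counts; always in [0, 1].
    """
    counts = np.asarray(v.counts, dtype=float)
    tic = counts.sum()
    if tic <= 0.0:
        raise UndefinedEnrichmentError(
            f"{v.metabolite}: TIC = 0, enrichment undefined (not detected)"
        )
    i = np.arange(v.c + 1)
    rlc = float(np.dot(counts, i))
    rtc = float(v.c * tic)
    return rlc / rtc


def enrichment_result(v: IsotopologueVector) -> EnrichmentResult:
    """Compute MDV, FC, RLC and RTC together for one vector."""
    mdv = compute_mdv(v)
    counts = np.asarray(v.counts, dtype=float)
    i = np.arange(v.c + 1)
    rlc = float(np.dot(counts, i))
    rtc = float(v.c * counts.sum())
    return EnrichmentResult(
        metabolite=v.metabolite,
        mdv=tuple(mdv),
        fc=rlc / rtc,
        rlc=rlc,
        rtc=rtc,
        time_min=v.time_min,
        biological_replicate=v.biological_replicate,
        technical_replicate=v.technical_replicate,
    )


def natural_abundance_matrix(c: int, p_na: float) -> np.ndarray:
    """Binomial convolution matrix C mapping a tracer-only MDV to an observed MDV.

    ``C[j, i]`` is the probability that a molecule with ``i`` tracer-labeled
    carbons is observed as isotopologue ``j`` once each of its ``c - i``
    unlabeled positions independently carries 13C at natural abundance
    ``p_na``: ``Binom(c - i, j - i) * p_na**(j-i) * (1-p_na)**(c-j)`` for
    ``j >= i``.  Lower triangular with positive diagonal, hence invertible
    for ``p_na < 1``.
    """
    if not 0.0 <= p_na < 0.5:
        raise ValueError(f"p_na must be in [0, 0.5), got {p_na}")
    C = np.zeros((c + 1, c + 1))
    for i in range(c + 1):
        extra = np.arange(c - i + 1)
        C[i + extra, i] = stats.binom.pmf(extra, c - i, p_na)
    return C


def natural_abundance_vector(c: int, p_na: float) -> np.ndarray:
    """MDV of a fully unlabeled pool at natural abundance: Binomial(c, p_na)."""
    return stats.binom.pmf(np.arange(c + 1), c, p_na)


def correct_natural_abundance(
    v: IsotopologueVector, p_na: float = NATURAL_13C_ABUNDANCE
) -> IsotopologueVector:
    """Deconvolve 13C natural abundance from raw isotopologue counts.

    Solves ``C x = counts`` where ``C`` is :func:`natural_abundance_matrix`,
    clips negative solutions to zero and rescales to the original TIC.  With
    ``p_na = 0`` the input is returned unchanged.  Clip-and-renormalize is
    used instead of constrained least squares; for carbon backbones up to
    c ~ 7 the difference is negligible and the arithmetic stays transparent.
    """
    if p_na == 0.0:
        return v
    counts = np.asarray(v.counts, dtype=float)
    C = natural_abundance_matrix(v.c, p_na)
    # Lower-triangular with diagonal (1-p)^c > 0: always solvable; guard anyway.
    try:
        x = np.linalg.solve(C, counts)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - cannot occur for p<0.5
        raise ValueError(f"natural-abundance matrix singular for p_na={p_na}") from exc
    x = np.clip(x, 0.0, None)
    total = x.sum()
    tic = counts.sum()
    if total > 0 and tic > 0:
        x *= tic / total
    return IsotopologueVector(
        metabolite=v.metabolite,
        c=v.c,
        counts=tuple(x),
        time_min=v.time_min,
        biological_replicate=v.biological_replicate,
        technical_replicate=v.technical_replicate,
    )


def normalize_per_cell(
    tic: float, cell_density: float, metabolite: str = ""
) -> PoolMeasurement:
    """Per-cell relative abundance: total ion count / cell density (cells/ml)."""
    if cell_density <= 0:
        raise ValueError(f"cell_density must be > 0, got {cell_density}")
    if tic < 0:
        raise ValueError(f"tic must be >= 0, got {tic}")
    return PoolMeasurement(
        metabolite=metabolite,
        tic=float(tic),
        cell_density=float(cell_density),
        relative_abundance=float(tic) / float(cell_density),
    )


def summarize_replicates(
    results: Iterable[EnrichmentResult],
) -> ReplicateSummary:
    """Roll replicate-level enrichment results up to condition level.

    MDVs are averaged across technical replicates within each biological
    replicate (mirroring how replicate MDV panels are reported); the FC for a
    biological replicate is the mean of its technical-replicate FCs, and the
    condition-level FC is the mean +/- sample SD (n-1 denominator) across
    biological replicates.  With a single biological replicate the SD is
    undefined and the summary is flagged.
    """
    results = list(results)
    if not results:
        raise ValueError("no enrichment results to summarize")
    metabolite = results[0].metabolite
    by_bio: dict[object, list[EnrichmentResult]] = {}
    for r in results:
        if r.metabolite != metabolite:
            raise ValueError("summarize_replicates expects a single metabolite")
        by_bio.setdefault(r.biological_replicate, []).append(r)
    mdv_by_bio = {}
    fc_by_bio = {}
    for bio, group in by_bio.items():
        if not group:
            raise ValueError(f"empty technical-replicate group for {bio!r}")
        mdvs = np.array([g.mdv for g in group], dtype=float)
        mdv_by_bio[bio] = tuple(mdvs.mean(axis=0))
        fc_by_bio[bio] = float(np.mean([g.fc for g in group]))
    fcs = np.array(list(fc_by_bio.values()), dtype=float)
    n_bio = len(fcs)
    fc_sd = float(np.std(fcs, ddof=1)) if n_bio > 1 else float("nan")
    return ReplicateSummary(
        metabolite=metabolite,
        mdv_by_biological=mdv_by_bio,
        fc_by_biological=fc_by_bio,
        fc_mean=float(fcs.mean()),
        fc_sd=fc_sd,
        n_biological=n_bio,
        single_replicate=n_bio < 2,
    )


# ---------------------------------------------------------------------------
# Table-level driver used by the CLI and the pipeline
# ---------------------------------------------------------------------------

_KEY_COLS = [
    "metabolite",
    "condition",
    "biological_replicate",
    "technical_replicate",
    "time_min",
]


def vectors_from_table(table: pd.DataFrame) -> list[IsotopologueVector]:
    """Build :class:`IsotopologueVector` objects from a tidy isotopologue table.

    The table must carry columns metabolite, i, c, condition,
    biological_replicate, technical_replicate, time_min, ion_count with a
    complete ``i = 0..c`` block per sample (validated by ``workflow_io``).
    """
    vectors = []
    for key, grp in table.groupby(_KEY_COLS, sort=True):
        met, cond, bio, tech, t = key
        grp = grp.sort_values("i")
        c = int(grp["c"].iloc[0])
        vectors.append(
            IsotopologueVector(
                metabolite=str(met),
                c=c,
                counts=tuple(grp["ion_count"].to_numpy(dtype=float)),
                time_min=float(t),
                biological_replicate=(cond, bio),
                technical_replicate=tech,
            )
        )
    return vectors


def enrich_table(
    table: pd.DataFrame,
    *,
    na_correction: bool = False,
    p_na: float = NATURAL_13C_ABUNDANCE,
    cell_density: Mapping[str, float] | float | None = None,
) -> dict[str, pd.DataFrame]:
    """Compute MDV/FC (and optionally per-cell pools) for a tidy table.

    Returns a dict of data frames: ``"fc"`` one row per sample, ``"mdv"``
    one row per isotopologue, ``"summary"`` condition-level FC mean/SD, and
    ``"pools"`` per-cell relative abundances when ``cell_density`` is given
    (a scalar, or a mapping from condition name to cells/ml).
    """
    fc_rows, mdv_rows, pool_rows = [], [], []
    undetected = []
    for key, grp in table.groupby(_KEY_COLS, sort=True):
        met, cond, bio, tech, t = key
        grp = grp.sort_values("i")
        c = int(grp["c"].iloc[0])
        v = IsotopologueVector(
            metabolite=str(met),
            c=c,
            counts=tuple(grp["ion_count"].to_numpy(dtype=float)),
            time_min=float(t),
            biological_replicate=bio,
            technical_replicate=tech,
        )
        if v.tic <= 0:
            undetected.append(key)
            continue
        if na_correction:
            v = correct_natural_abundance(v, p_na)
        res = enrichment_result(v)
        base = dict(
            metabolite=met,
            condition=cond,
            biological_replicate=bio,
            technical_replicate=tech,
            time_min=t,
        )
        fc_rows.append({**base, "fc": res.fc, "rlc": res.rlc, "rtc": res.rtc, "tic": v.tic})
        for i, m in enumerate(res.mdv):
            mdv_rows.append({**base, "i": i, "mdv": m})
        if cell_density is not None:
            density = (
                cell_density if np.isscalar(cell_density) else cell_density[cond]
            )
            pm = normalize_per_cell(v.tic, float(density), metabolite=str(met))
            pool_rows.append({**base, "tic": pm.tic, "relative_abundance": pm.relative_abundance})

    fc = pd.DataFrame(fc_rows)
    out = {"fc": fc, "mdv": pd.DataFrame(mdv_rows)}
    if not fc.empty:
        per_bio = (
            fc.groupby(["metabolite", "condition", "time_min", "biological_replicate"])["fc"]
            .mean()
            .reset_index()
        )
        summary = (
            per_bio.groupby(["metabolite", "condition", "time_min"])["fc"]
            .agg(fc_mean="mean", fc_sd=lambda s: s.std(ddof=1), n_biological="count")
            .reset_index()
        )
        out["summary"] = summary
    else:
        out["summary"] = pd.DataFrame()
    if cell_density is not None:
        out["pools"] = pd.DataFrame(pool_rows)
    if undetected:
        out["undetected"] = pd.DataFrame(undetected, columns=_KEY_COLS)
    return out
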