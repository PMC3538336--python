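"""Per-line phenotype aggregation and broad-sense heritability.

Accepted seed measurements are averaged per line (and per replicate
harvest where replicates exist); a line's final phenotype is the
unweighted mean of its replicate means. Broad-sense heritability is
estimated per trait by one-way random-effects ANOVA across lines:

    MS_M = between-line SS / (a - 1)
    MS_E = within-line SS / (N - a)
    n0   = (N - sum(n_i^2)/N) / (a - 1)      effective group size
    V_A  = max(0, (MS_M - MS_E) / n0)
    H2   = V_A / (V_A + V_E)

where a is the number of lines, n_i the seeds per line, N the total.
Between-line variance captures genetic differences among near-homozygous
lines, within-line variance the environmental noise. The default
environmental-variance estimator is MS_E (labeled ``V_E_method=MS_E``);
H2 can also be computed directly from externally estimated (V_A, V_E)
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LinePhenotype",
    "HeritabilityResult",
    "TRAITS",
    "line_means",
    "replicate_average",
    "aggregate_records",
    "variance_components",
    "heritability",
    "heritability_report",
    "export_phenotypes",
]

logger = logging.getLogger(__name__)

#: Trait columns produced by morphometry, in canonical order.
TRAITS = {"area": "area_mm2", "major_axis": "major_mm", "minor_axis": "minor_mm"}


@dataclass(frozen=True)
class LinePhenotype:
    line_id: str
    replicate_id: str | None
    n_seeds: int
    mean_area_mm2: float
    mean_major_mm: float
    mean_minor_mm: float
    sd_area_mm2: float
    sd_major_mm: float
    sd_minor_mm: float


@dataclass(frozen=True)
class HeritabilityResult:
    """One-way ANOVA summary and variance components for one trait."""

    trait: str
    ms_model: float
    ms_error: float
    df_model: int
    df_error: int
    n0: float
    v_a: float
    v_e: float
    h2: float
    v_e_method: str = "MS_E"


def line_means(records: pd.DataFrame) -> list[LinePhenotype]:
    """Per-(line, replicate) means and standard deviations of the traits.

    ``records`` needs columns ``line_id``, the three trait columns
    (``area_mm2``, ``major_mm``, ``minor_mm``) and optionally
    ``replicate_id``; only rows the filters accepted should be passed in.
    Empty groups cannot arise from a groupby, but all-NaN groups are
    skipped with a warning.
    """
    has_rep = "replicate_id" in records.columns
    keys = ["line_id", "replicate_id"] if has_rep else ["line_id"]
    out: list[LinePhenotype] = []
    for key, grp in records.groupby(keys, sort=True):
        if not has_rep:
            key = (key[0] if isinstance(key, tuple) else key, None)
        if grp["area_mm2"].isna().all():
            logger.warning("group %s has no usable measurements; skipped", key)
            continue
        out.append(
            LinePhenotype(
                line_id=str(key[0]),
                replicate_id=None if key[1] is None else str(key[1]),
                n_seeds=int(len(grp)),
                mean_area_mm2=float(grp["area_mm2"].mean()),
                mean_major_mm=float(grp["major_mm"].mean()),
                mean_minor_mm=float(grp["minor_mm"].mean()),
                sd_area_mm2=float(grp["area_mm2"].std(ddof=1)) if len(grp) > 1 else 0.0,
                sd_major_mm=float(grp["major_mm"].std(ddof=1)) if len(grp) > 1 else 0.0,
                sd_minor_mm=float(grp["minor_mm"].std(ddof=1)) if len(grp) > 1 else 0.0,
            )
        )
    return out


def replicate_average(phenos: Sequence[LinePhenotype]) -> pd.DataFrame:
    """Final per-line values: unweighted mean of the replicate means.

    Each replicate counts equally regardless of how many seeds it
    contributed (replicate-level averaging, not a pooled per-seed mean).
    Returns one row per line with columns ``line_id``, ``area``,
    ``major_axis``, ``minor_axis``, ``n_seeds``, ``n_replicates``.
    """
    df = pd.DataFrame(
        {
            "line_id": [p.line_id for p in phenos],
            "area": [p.mean_area_mm2 for p in phenos],
            "major_axis": [p.mean_major_mm for p in phenos],
            "minor_axis": [p.mean_minor_mm for p in phenos],
            "n_seeds": [p.n_seeds for p in phenos],
        }
    )
    agg = df.groupby("line_id", sort=True).agg(
        area=("area", "mean"),
        major_axis=("major_axis", "mean"),
        minor_axis=("minor_axis", "mean"),
        n_seeds=("n_seeds", "sum"),
        n_replicates=("area", "size"),
    )
    return agg.reset_index()


def aggregate_records(records: pd.DataFrame, mode: str = "replicate-mean") -> pd.DataFrame:
    """Aggregate accepted seed records to final per-line trait values.

    ``mode='replicate-mean'`` (default) averages replicate means with
    equal weight; ``mode='pooled'`` averages over all seeds of a line
    regardless of replicate, weighting replicates by their seed counts.
    """
    if mode == "replicate-mean":
        return replicate_average(line_means(records))
    if mode == "pooled":
        pooled = records.copy()
        pooled = pooled.drop(columns=["replicate_id"], errors="ignore")
        phenos = line_means(pooled)
        return replicate_average(phenos)
    raise ValueError(f"unknown aggregation mode: {mode!r}")


def _groups_from(values) -> list[np.ndarray]:
    if isinstance(values, pd.DataFrame):
        if not {"line_id", "value"} <= set(values.columns):
            raise ValueError("DataFrame input needs 'line_id' and 'value' columns")
        return [np.asarray(g, dtype=float) for _, g in values.groupby("line_id")["value"]]
    if isinstance(values, Mapping):
        return [np.asarray(v, dtype=float) for v in values.values()]
    raise TypeError("values must be a mapping line->array or a line_id/value DataFrame")


def variance_components(values, trait: str = "trait", v_e: float | None = None) -> HeritabilityResult:
    """One-way ANOVA variance components across lines for one trait.

    ``values`` maps each line to its per-seed trait values (a mapping or
    a ``line_id``/``value`` DataFrame). The between-line mean square in
    excess of the within-line mean square, scaled by the effective group
    size ``n0`` (equal to n for balanced designs), estimates the genetic
    variance ``V_A``; a negative moment estimate is floored at zero.
    ``v_e`` overrides the default environmental-variance estimator MS_E.
    """
    groups = _groups_from(values)
    a = len(groups)
    if a < 2:
        raise ValueError("at least 2 lines are required")
    sizes = np.array([g.size for g in groups], dtype=float)
    if (sizes == 0).any():
        raise ValueError("every line must have at least one observation")
    n_total = float(sizes.sum())
    if n_total - a < 1:
        raise ValueError("need at least one within-line degree of freedom")

    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_m = a - 1
    df_e = int(n_total) - a
    ms_m = ss_between / df_m
    ms_e = ss_within / df_e
    n0 = (n_total - float(np.sum(sizes**2)) / n_total) / df_m
    v_a = max(0.0, (ms_m - ms_e) / n0)
    v_e_val = ms_e if v_e is None else float(v_e)
    # H2 is undefined when there is no variance at all
    h2 = heritability(v_a, v_e_val) if v_a + v_e_val > 0 else float("nan")
    return HeritabilityResult(
        trait=trait,
        ms_model=ms_m,
        ms_error=ms_e,
        df_model=df_m,
        df_error=df_e,
        n0=n0,
        v_a=v_a,
        v_e=v_e_val,
        h2=h2,
        v_e_method="MS_E" if v_e is None else "user",
    )


def heritability(v_a: float, v_e: float) -> float:
    """Broad-sense heritability H2 = V_A / (V_A + V_E)."""
    if v_a < 0 or v_e < 0:
        raise ValueError("variance components must be nonnegative")
    total = v_a + v_e
    if total <= 0:
        raise ValueError("V_A + V_E must be positive for H2 to be defined")
    return v_a / total


def heritability_report(
    seed_values: pd.DataFrame,
    trait_columns: Mapping[str, str] = TRAITS,
    v_e: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """ANOVA heritability for each trait, one table row per trait.

    ``seed_values`` holds one row per seed with ``line_id`` plus the
    trait columns. Output columns mirror the standard variance-component
    summary: trait, MS_M, MS_E, df_M, df_E, n0, V_A, V_E, H2, V_E_method.
    """
    rows = []
    for trait, col in trait_columns.items():
        df = seed_values[["line_id", col]].rename(columns={col: "value"}).dropna()
        res = variance_components(
            df, trait=trait, v_e=None if v_e is None else v_e.get(trait)
        )
        rows.append(
            {
                "trait": res.trait,
                "MS_M": res.ms_model,
                "MS_E": res.ms_error,
                "df_M": res.df_model,
                "df_E": res.df_error,
                "n0": res.n0,
                "V_A": res.v_a,
                "V_E": res.v_e,
                "H2": round(res.h2, 3),
                "V_E_method": res.v_e_method,
            }
        )
    return pd.DataFrame(rows)


def export_phenotypes(final_values: pd.DataFrame, path: str | Path) -> None:
    """Write the per-line phenotype table, sorted by line id.

    Columns: line_id, area, major_axis, minor_axis, n_seeds,
    n_replicates — a block that pastes into a standard QTL cross file.
    """
    if final_values.empty:
        raise ValueError("no line phenotypes to export")
    cols = ["line_id", "area", "major_axis", "minor_axis", "n_seeds", "n_replicates"]
    out = final_values[cols].sort_values("line_id").reset_index(drop=True)
    out.to_csv(path, index=False, float_format="%.6g")
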