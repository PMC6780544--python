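"""Sample:IS ratio quantitation, imputation, and regulation classification.

Because every run carries the same pooled heavy-labeled internal standard,
the ratio of a metabolite's sample-channel area to its IS-channel area is an
injection- and extraction-normalized abundance.  Comparing treatment ratios
(T:IS) against control ratios (C:IS) then reads out regulation, including
the on/off cases that an unpooled design cannot see: a metabolite produced
only under treatment still has an IS partner, so its absence from controls
is a measurable missing value rather than an invisible one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formula_id import Formula, adduct_mz, monoisotopic_mass, ADDUCTS
from .peak_pairing import PairTable

__all__ = [
    "RatioMatrix",
    "RegulationCall",
    "TargetEntry",
    "compute_ratios",
    "impute_missing",
    "log2_fold_change",
    "classify_regulation",
    "targeted_extract",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("initiated", "terminated", "upregulated", "downregulated", "unchanged")


@dataclass
class RatioMatrix:
    """Metabolites x samples matrix of sample:IS area ratios.

    ``ratios`` holds NaN for cells that were missing or sub-LOQ before
    imputation; ``imputed_mask`` marks those cells; ``groups`` maps each
    sample column to ``treatment`` or ``control``; ``unquantifiable`` flags
    rows whose IS channel was below LOQ in at least half the runs.
    """

    ratios: pd.DataFrame
    groups: pd.Series
    imputed_mask: pd.DataFrame
    loq: float
    unquantifiable: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.unquantifiable is None:
            self.unquantifiable = pd.Series(False, index=self.ratios.index)
        missing = set(self.ratios.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.ratios.columns if self.groups[s] == group]


@dataclass(frozen=True)
class RegulationCall:
    row_id: str
    category: str
    log2fc: float
    p_value: float


def compute_ratios(
    table: PairTable,
    groups: pd.Series,
    loq: float = 0.0,
) -> RatioMatrix:
    """Raw sample:IS ratios from an aligned pair table.

    A cell is ``area_sample / area_is`` when both areas are present and at
    least LOQ; otherwise it is missing (NaN) and flagged for imputation.
    Rows whose IS area is absent or sub-LOQ in half or more of the runs are
    flagged unquantifiable — their IS reference cannot be trusted.
    """
    if loq < 0:
        raise ValueError("loq must be >= 0")
    a_s = table.area_sample
    a_i = table.area_is
    ok = (a_s >= loq) & (a_i >= loq) & (a_i > 0) & a_s.notna() & a_i.notna()
    ratios = (a_s / a_i).where(ok)
    mask = ~ok
    is_bad = (a_i.isna() | (a_i < loq)).sum(axis=1)
    unquant = is_bad >= (a_i.shape[1] / 2.0)
    return RatioMatrix(
        ratios=ratios,
        groups=groups,
        imputed_mask=mask,
        loq=loq,
        unquantifiable=unquant,
    )


def impute_missing(matrix: RatioMatrix) -> RatioMatrix:
    """Replace each missing cell by half the row's minimum observed ratio.

    A conservative floor imputation: a censored cell was below the
    quantitation limit, so it gets a value strictly below everything that
    was observed in that row.  Rows with no observed cell at all cannot be
    imputed and are dropped (logged).
    """
    obs_min = matrix.ratios.min(axis=1, skipna=True)
    dead = obs_min.isna()
    if dead.any():
        logger.info("dropping %d fully-missing rows", int(dead.sum()))
    keep = ~dead
    ratios = matrix.ratios.loc[keep].copy()
    mask = matrix.imputed_mask.loc[keep]
    fill = obs_min.loc[keep] / 2.0
    ratios = ratios.apply(lambda col: col.fillna(fill))
    return RatioMatrix(
        ratios=ratios,
        groups=matrix.groups,
        imputed_mask=mask,
        loq=matrix.loq,
        unquantifiable=matrix.unquantifiable.loc[keep],
    )


def log2_fold_change(
    matrix: RatioMatrix,
    mean: str = "arithmetic",
) -> pd.Series:
    """Per-row log2(mean treatment ratio / mean control ratio).

    Arithmetic means by default; ``mean="geometric"`` averages on the log
    scale instead.
    """
    t_cols = matrix.group_columns("treatment")
    c_cols = matrix.group_columns("control")
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    t = matrix.ratios[t_cols]
    c = matrix.ratios[c_cols]
    if mean == "arithmetic":
        t_m, c_m = t.mean(axis=1), c.mean(axis=1)
        assert (t_m > 0).all() and (c_m > 0).all(), "nonpositive mean after imputation"
        fc = np.log2(t_m / c_m)
    elif mean == "geometric":
        fc = np.log2(t).mean(axis=1) - np.log2(c).mean(axis=1)
    else:
        raise ValueError(f"unknown mean {mean!r}")
    fc.name = "log2fc"
    return fc


def classify_regulation(
    matrix: RatioMatrix,
    p_values: pd.Series,
    fc_threshold: float = 1.0,
    alpha: float = 0.001,
) -> list[RegulationCall]:
    """Call each metabolite initiated / terminated / up / down / unchanged.

    ``initiated``: every control cell was imputed from missing while the
    treatment channel was observed in at least half its runs — production
    switched on.  ``terminated`` is the mirror.  Otherwise the call is
    up/down when \\|log2fc\\| >= ``fc_threshold`` and p <= ``alpha``, else
    unchanged.
    """
    fc = log2_fold_change(matrix)
    t_cols = matrix.group_columns("treatment")
    c_cols = matrix.group_columns("control")
    calls = []
    for row_id in matrix.ratios.index:
        c_imp = matrix.imputed_mask.loc[row_id, c_cols]
        t_imp = matrix.imputed_mask.loc[row_id, t_cols]
        l2fc = float(fc[row_id])
        p = float(p_values.get(row_id, np.nan))
        if c_imp.all() and (~t_imp).sum() >= len(t_cols) / 2.0:
            cat = "initiated"
        elif t_imp.all() and (~c_imp).sum() >= len(c_cols) / 2.0:
            cat = "terminated"
        elif abs(l2fc) >= fc_threshold and p <= alpha:
            cat = "upregulated" if l2fc > 0 else "downregulated"
        else:
            cat = "unchanged"
        calls.append(RegulationCall(row_id=row_id, category=cat, log2fc=l2fc, p_value=p))
    return calls


@dataclass(frozen=True)
class TargetEntry:
    """One targeted-panel compound: name, neutral formula, candidate adducts."""

    name: str
    formula: Formula
    adducts: tuple[str, ...] = ("[M+H]+",)
    pathway_position: str = ""


def targeted_extract(
    table: PairTable,
    panel: list[TargetEntry],
    matrix: RatioMatrix,
    ppm_tol: float = 10.0,
) -> pd.DataFrame:
    """Look up a targeted compound panel in the aligned pair table.

    For each panel entry, rows are matched on exact carbon count and on any
    adduct m/z within ``ppm_tol``; the closest-m/z row wins (ambiguity is
    logged).  Output is a long-format frame with ``found`` flags and the
    treatment-vs-control log2 fold change of the matched row — entries with
    no match mirror pathway intermediates that were simply not detected.
    """
    fc = log2_fold_change(matrix)
    out = []
    for entry in panel:
        mass = monoisotopic_mass(entry.formula)
        n_c = entry.formula.C
        candidates = []
        for row_id, feat in table.features.iterrows():
            if int(feat["carbon_count"]) != n_c:
                continue
            for ad_name in entry.adducts:
                ad = ADDUCTS[ad_name]
                if ad.polarity != feat["polarity"]:
                    continue
                expected = adduct_mz(mass, ad)
                err = abs(feat["mz12"] - expected)
                if err <= ppm_tol * 1e-6 * expected:
                    candidates.append((err, row_id, ad_name))
        rec = {
            "name": entry.name,
            "formula": str(entry.formula),
            "pathway_position": entry.pathway_position,
            "found": bool(candidates),
            "row_id": None,
            "adduct": None,
            "log2fc": np.nan,
        }
        if candidates:
            candidates.sort()
            if len(candidates) > 1:
                logger.debug(
                    "targeted entry %s matched %d rows; keeping closest m/z",
                    entry.name, len(candidates),
                )
            _, row_id, ad_name = candidates[0]
            rec["row_id"] = row_id
            rec["adduct"] = ad_name
            if row_id in fc.index:
                rec["log2fc"] = float(fc[row_id])
        out.append(rec)
    return pd.DataFrame(out)
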