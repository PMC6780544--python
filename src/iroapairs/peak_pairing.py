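"""Detection of 12C/13C peak pairs in centroided LC/MS runs.

A dual-label run contains, for every true metabolite, two co-eluting
isotopologue clusters: a light cluster from the sample culture (binomial
envelope peaking at the all-12C species) and a heavy cluster from the pooled
internal standard (mirrored envelope peaking at the all-13C species).  The
m/z gap between the two monoisotopic species equals
``carbon_count * 1.0033548 / z``.  Signals without a partner at such a gap —
solvent ions, adduct debris, electronic noise — are discarded, which is the
artifact-exclusion property of the design.

Pipeline order: :func:`cluster_isotopologues` chains peaks into clusters,
:func:`classify_cluster_channel` calls each cluster sample/IS from its
envelope shape, :func:`find_peak_pairs` matches the channels into
:class:`PeakPair` records, and :func:`align_pairs_across_samples` assembles
the per-run pairs into one :class:`PairTable` of metabolites x samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotope_model import (
    DELTA_C13,
    LabelingScheme,
    carbon_isotopologue_envelope,
    envelope_similarity,
    estimate_carbon_count,
    isotopologue_spacing,
)

__all__ = [
    "CentroidPeak",
    "IsotopologueCluster",
    "PeakPair",
    "PairTable",
    "cluster_isotopologues",
    "classify_cluster_channel",
    "find_peak_pairs",
    "align_pairs_across_samples",
]

logger = logging.getLogger(__name__)

_template_cache: dict[tuple[int, float], np.ndarray] = {}


def _template(n: int, p13: float) -> np.ndarray:
    """Memoized binomial envelope (classification sweeps many candidate n)."""
    key = (n, p13)
    if key not in _template_cache:
        _template_cache[key] = carbon_isotopologue_envelope(n, p13)
    return _template_cache[key]


@dataclass(frozen=True)
class CentroidPeak:
    """One centroided (m/z, RT, area) observation from one run."""

    mz: float
    rt: float
    intensity: float
    sample_id: str = ""
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.rt < 0 or self.intensity <= 0:
            raise ValueError("require mz > 0, rt >= 0, intensity > 0")


@dataclass
class IsotopologueCluster:
    """Co-eluting peaks spaced by the 13C gap, ordered by m/z."""

    peaks: list[CentroidPeak]
    charge: int = 1
    channel: str = "unclassified"  # sample | is | unclassified
    channel_score: float = 0.0
    n_best: int = 0

    @property
    def base_mz(self) -> float:
        return self.peaks[0].mz

    @property
    def top_mz(self) -> float:
        return self.peaks[-1].mz

    @property
    def rt_apex(self) -> float:
        """RT of the most intense member."""
        return max(self.peaks, key=lambda p: p.intensity).rt

    @property
    def envelope(self) -> np.ndarray:
        v = np.array([p.intensity for p in self.peaks], dtype=float)
        return v / v.sum()

    @property
    def total_area(self) -> float:
        return float(sum(p.intensity for p in self.peaks))


@dataclass(frozen=True)
class PeakPair:
    """A matched 12C/13C cluster pair — the unit 'metabolite' in one run."""

    carbon_count: int
    mono12_mz: float
    mono13_mz: float
    rt: float
    polarity: str
    area_sample: float
    area_is: float
    pair_score: float
    sample_id: str


@dataclass
class PairTable:
    """Aligned metabolites x samples table of peak-pair areas.

    ``features`` is indexed by row_id with the consensus coordinates
    (polarity, carbon_count, mz12, mz13, rt_sec); ``area_sample`` and
    ``area_is`` share that index with one column per run; missing cells are
    NaN.
    """

    features: pd.DataFrame
    area_sample: pd.DataFrame
    area_is: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.area_sample.columns)

    def to_pairs(self) -> dict[str, list[PeakPair]]:
        """Explode the table back into per-run pair lists (inverse of alignment)."""
        out: dict[str, list[PeakPair]] = {s: [] for s in self.sample_ids}
        for row_id, feat in self.features.iterrows():
            for s in self.sample_ids:
                a_s, a_i = self.area_sample.at[row_id, s], self.area_is.at[row_id, s]
                if np.isnan(a_s) or np.isnan(a_i):
                    continue
                out[s].append(
                    PeakPair(
                        carbon_count=int(feat["carbon_count"]),
                        mono12_mz=float(feat["mz12"]),
                        mono13_mz=float(feat["mz13"]),
                        rt=float(feat["rt_sec"]),
                        polarity=str(feat["polarity"]),
                        area_sample=float(a_s),
                        area_is=float(a_i),
                        pair_score=1.0,
                        sample_id=s,
                    )
                )
        return out

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format pairs table (one row per filled cell) for CSV export."""
        rows = []
        for row_id, feat in self.features.iterrows():
            for s in self.sample_ids:
                a_s, a_i = self.area_sample.at[row_id, s], self.area_is.at[row_id, s]
                if np.isnan(a_s) or np.isnan(a_i):
                    continue
                rows.append(
                    {
                        "row_id": row_id,
                        "polarity": feat["polarity"],
                        "carbon_count": int(feat["carbon_count"]),
                        "mz12": feat["mz12"],
                        "mz13": feat["mz13"],
                        "rt_sec": feat["rt_sec"],
                        "sample_id": s,
                        "area_sample": a_s,
                        "area_is": a_i,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 1: isotopologue clustering


def cluster_isotopologues(
    peaks: list[CentroidPeak],
    ppm_tol: float = 10.0,
    rt_tol: float = 6.0,
    charges: frozenset[int] | set[int] = frozenset({1}),
) -> list[IsotopologueCluster]:
    """Greedily chain peaks of one run into isotopologue clusters.

    Peaks are visited in ascending m/z; a peak joins an open cluster when its
    m/z sits one 13C spacing above the cluster's last member (within
    ``ppm_tol`` of the expected m/z) and its RT is within ``rt_tol`` seconds
    of the cluster apex.  Every peak ends up in exactly one cluster;
    singletons are allowed.
    """
    ordered = sorted(peaks, key=lambda p: (p.mz, p.rt))
    max_spacing = isotopologue_spacing(min(charges))
    closed: list[IsotopologueCluster] = []
    active: list[IsotopologueCluster] = []
    for peak in ordered:
        # clusters whose next expected member is already below this m/z can
        # never grow again (peaks ascend) — retire them
        still = []
        for cl in active:
            last = cl.peaks[-1].mz
            if peak.mz - last > max_spacing + ppm_tol * 1e-6 * (peak.mz + last):
                closed.append(cl)
            else:
                still.append(cl)
        active = still
        best = None  # (mz deviation, cluster, charge)
        for cl in active:
            for z in sorted(charges):
                if len(cl.peaks) > 1 and z != cl.charge:
                    continue  # charge fixed by the first accepted gap
                expected = cl.peaks[-1].mz + isotopologue_spacing(z)
                dev = abs(peak.mz - expected)
                # window on the sum of the two centroid m/z's: the link error
                # is the difference of two noisy centroids
                if dev <= ppm_tol * 1e-6 * (cl.peaks[-1].mz + peak.mz) and abs(
                    peak.rt - cl.rt_apex
                ) <= rt_tol:
                    if best is None or dev < best[0]:
                        best = (dev, cl, z)
        if best is None:
            active.append(IsotopologueCluster(peaks=[peak]))
        else:
            _, cl, z = best
            cl.peaks.append(peak)
            cl.charge = z
    closed.extend(active)
    closed.sort(key=lambda c: (c.base_mz, c.rt_apex))
    return closed


# ---------------------------------------------------------------------------
# stage 2: channel classification


def classify_cluster_channel(
    cluster: IsotopologueCluster,
    scheme: LabelingScheme = LabelingScheme(),
    min_score: float = 0.95,
    max_carbons: int = 60,
) -> str:
    """Call a cluster sample / IS / unclassified from its envelope shape.

    The observed envelope is compared against binomial templates for every
    candidate carbon count: front-aligned against ``Binomial(n, p13_sample)``
    for the sample channel, and reversed against ``Binomial(n, 1 - p13_is)``
    for the IS channel (by mirror symmetry the heavy envelope read from its
    top is the light envelope).  The channel with the higher best cosine
    wins if it reaches ``min_score``.

    Single-member clusters stay unclassified: a lone centroid carries no
    envelope information, and refusing to call it is what keeps unpaired
    artifact signals out of the downstream pair search.
    """
    if not cluster.peaks:
        raise ValueError("cluster has no members")
    if len(cluster.peaks) < 2:
        cluster.channel, cluster.channel_score, cluster.n_best = "unclassified", 0.0, 0
        return cluster.channel
    obs = cluster.envelope
    n_lo = max(1, len(obs) - 1)
    best_sample = (0.0, 0)
    best_is = (0.0, 0)
    for n in range(n_lo, max_carbons + 1):
        t = _template(n, scheme.p13_sample)
        s = envelope_similarity(obs, t)
        if s > best_sample[0]:
            best_sample = (s, n)
        t_is = _template(n, 1.0 - scheme.p13_is)
        s_is = envelope_similarity(obs[::-1], t_is)
        if s_is > best_is[0]:
            best_is = (s_is, n)
    if best_sample[0] >= best_is[0]:
        score, n_best, channel = *best_sample, "sample"
    else:
        score, n_best, channel = *best_is, "is"
    if score < min_score or best_sample[0] == best_is[0]:
        channel, n_best = "unclassified", 0
    cluster.channel, cluster.channel_score, cluster.n_best = channel, float(score), n_best
    return channel


# ---------------------------------------------------------------------------
# stage 3: pairing


def _try_merged_pair(
    cluster: IsotopologueCluster,
    scheme: LabelingScheme,
    ppm_tol: float,
    n_range: tuple[int, int],
    min_score: float,
    area_mode: str,
    min_channel_frac: float = 0.10,
) -> PeakPair | None:
    """Decompose one contiguous cluster that holds both channels of a pair.

    For metabolites of few carbons the light and heavy envelopes interleave:
    the isotopologue ladder runs without a gap from the all-12C to the
    all-13C monoisotopic species, so chaining produces a single U-shaped
    cluster instead of two.  Such a cluster with L members is hypothesized
    to be an n = L - 1 carbon pair and its member intensities are decomposed
    by non-negative least squares onto the two binomial bases
    ``Binomial(n, p13_sample)`` and ``Binomial(n, p13_is)``.  The hypothesis
    is accepted when the modeled envelope matches the observed one at
    ``min_score`` cosine, both channels carry at least ``min_channel_frac``
    of the total area, and the base-to-top m/z gap agrees with n spacings.

    Both thresholds are deliberately strict: a one-sided envelope tail
    (e.g. the top three members of a heavy channel) can reach a cosine of
    ~0.97 against a small-n two-channel model while assigning only a few
    percent of the area to the phantom second channel, whereas a genuine
    two-channel ladder fits essentially exactly and splits its area no
    worse than ~1:10 for any plausible regulation effect.
    """
    from scipy.optimize import nnls

    n = len(cluster.peaks) - 1
    if not n_range[0] <= n <= n_range[1]:
        return None
    mz12, mz13 = cluster.base_mz, cluster.top_mz
    n_gap, _ = estimate_carbon_count(mz13 - mz12, cluster.charge, n_range[1])
    if n_gap != n:
        return None
    if abs((mz13 - mz12) - n * DELTA_C13 / cluster.charge) > ppm_tol * 1e-6 * (mz12 + mz13):
        return None
    obs = np.array([p.intensity for p in cluster.peaks], dtype=float)
    basis_s = _template(n, scheme.p13_sample)
    basis_i = _template(n, scheme.p13_is)
    coeffs, _ = nnls(np.column_stack([basis_s, basis_i]), obs)
    a_s, a_i = float(coeffs[0]), float(coeffs[1])
    model = a_s * basis_s + a_i * basis_i
    if model.sum() <= 0:
        return None
    if envelope_similarity(obs, model) < min_score:
        return None
    total = a_s + a_i
    if a_s < min_channel_frac * total or a_i < min_channel_frac * total:
        return None  # effectively single-channel — not a pair
    if area_mode == "summed":
        area_s, area_i = a_s, a_i
    else:
        area_s, area_i = a_s * basis_s[0], a_i * basis_i[-1]
    return PeakPair(
        carbon_count=n,
        mono12_mz=mz12,
        mono13_mz=mz13,
        rt=cluster.rt_apex,
        polarity=cluster.peaks[0].polarity,
        area_sample=area_s,
        area_is=area_i,
        pair_score=float(envelope_similarity(obs, model)),
        sample_id=cluster.peaks[0].sample_id,
    )


def find_peak_pairs(
    clusters: list[IsotopologueCluster],
    scheme: LabelingScheme = LabelingScheme(),
    ppm_tol: float = 10.0,
    rt_tol: float = 6.0,
    n_range: tuple[int, int] = (2, 60),
    area_mode: str = "summed",
    min_score: float = 0.95,
) -> list[PeakPair]:
    """Match sample-channel clusters with IS-channel clusters into pairs.

    Two geometries occur.  For metabolites of few carbons the two channels'
    envelopes form one contiguous ladder and arrive as a single cluster;
    those are resolved first by two-channel decomposition (see
    :func:`_try_merged_pair`).  For larger carbon counts the channels are
    separated by a run of sub-floor isotopologues and arrive as two
    clusters: for each sample-channel cluster, IS-channel clusters
    co-eluting within ``rt_tol`` are searched for a monoisotopic gap equal
    to ``n * 1.0033548 / z`` for some ``n`` in ``n_range``.  The gap window
    is ``ppm_tol`` applied to the sum of the two monoisotopic m/z values,
    which is the scale on which the mass error of the two centroids actually
    propagates into the gap.  The carbon count comes from the gap; a cluster
    whose envelope-fit carbon count disagrees with the gap by more than +-1
    is rejected.  Clusters without a partner are dropped — they are
    artifacts or below-floor signals by the logic of the labeling design.

    ``area_mode`` selects summed envelope area per channel (default) or
    ``"mono"`` for the monoisotopic member only.
    """
    if area_mode not in ("summed", "mono"):
        raise ValueError(f"unknown area_mode {area_mode!r}")
    n_min, n_max = n_range

    # index of every centroid in the run, for the ladder-end guard: a
    # candidate monoisotopic species must not have a co-eluting neighbour one
    # spacing outside the cluster, otherwise the cluster is a truncated
    # ladder (a broken chain) and its ends are not the monoisotopic ions
    all_peaks = sorted(
        ((p.mz, p.rt) for c in clusters for p in c.peaks), key=lambda t: t[0]
    )
    all_mz = np.array([t[0] for t in all_peaks])
    all_rt = np.array([t[1] for t in all_peaks])

    def _peak_near(mz: float, rt: float) -> bool:
        tol = ppm_tol * 1e-6 * 2 * mz
        lo = np.searchsorted(all_mz, mz - tol)
        hi = np.searchsorted(all_mz, mz + tol)
        return bool(np.any(np.abs(all_rt[lo:hi] - rt) <= rt_tol))

    def _is_ladder_start(cl: IsotopologueCluster) -> bool:
        return not _peak_near(cl.base_mz - isotopologue_spacing(cl.charge), cl.rt_apex)

    def _is_ladder_end(cl: IsotopologueCluster) -> bool:
        return not _peak_near(cl.top_mz + isotopologue_spacing(cl.charge), cl.rt_apex)

    pairs: list[PeakPair] = []
    unconsumed = []
    for cl in clusters:
        merged = None
        if len(cl.peaks) >= 3 and _is_ladder_start(cl) and _is_ladder_end(cl):
            merged = _try_merged_pair(
                cl, scheme, ppm_tol, (n_min, n_max), max(min_score, 0.99), area_mode
            )
        if merged is not None:
            pairs.append(merged)
        else:
            unconsumed.append(cl)
    sample_clusters = [
        c for c in unconsumed if c.channel == "sample" and _is_ladder_start(c)
    ]
    is_clusters = [c for c in unconsumed if c.channel == "is" and _is_ladder_end(c)]
    for sc in sample_clusters:
        candidates = []
        for ic in is_clusters:
            if ic.charge != sc.charge:
                continue
            rt_diff = abs(ic.rt_apex - sc.rt_apex)
            if rt_diff > rt_tol:
                continue
            mz12, mz13 = sc.base_mz, ic.top_mz
            gap = mz13 - mz12
            if gap <= 0:
                continue
            n, _ = estimate_carbon_count(gap, sc.charge, n_max)
            if not n_min <= n <= n_max:
                continue
            residual_da = abs(gap - n * DELTA_C13 / sc.charge)
            if residual_da > ppm_tol * 1e-6 * (mz12 + mz13):
                continue
            if sc.n_best and abs(sc.n_best - n) > 1:
                logger.debug(
                    "pair rejected: gap n=%d vs sample envelope n=%d at mz %.4f",
                    n, sc.n_best, mz12,
                )
                continue
            if ic.n_best and abs(ic.n_best - n) > 1:
                logger.debug(
                    "pair rejected: gap n=%d vs IS envelope n=%d at mz %.4f",
                    n, ic.n_best, mz13,
                )
                continue
            candidates.append((residual_da, rt_diff, -ic.total_area, n, ic))
        if not candidates:
            continue
        candidates.sort(key=lambda c: c[:3])
        _, _, _, n, ic = candidates[0]
        if area_mode == "summed":
            area_s, area_i = sc.total_area, ic.total_area
        else:
            area_s, area_i = sc.peaks[0].intensity, ic.peaks[-1].intensity
        pairs.append(
            PeakPair(
                carbon_count=n,
                mono12_mz=sc.base_mz,
                mono13_mz=ic.top_mz,
                rt=sc.rt_apex,
                polarity=sc.peaks[0].polarity,
                area_sample=area_s,
                area_is=area_i,
                pair_score=0.5 * (sc.channel_score + ic.channel_score),
                sample_id=sc.peaks[0].sample_id,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# stage 4: cross-run alignment


def align_pairs_across_samples(
    per_run_pairs: dict[str, list[PeakPair]],
    ppm_tol: float = 10.0,
    rt_tol: float = 6.0,
) -> PairTable:
    """Align per-run pair lists into one metabolite x sample table.

    Rows are seeded from the run with the most pairs; a pair from another
    run joins a row when the carbon count matches exactly and m/z and RT
    fall within tolerance, best m/z distance first.  Unmatched pairs open
    new rows.  Two pairs of one run landing on one row is a collision: the
    higher pair_score wins and the event is logged.
    """
    run_order = sorted(per_run_pairs, key=lambda s: (-len(per_run_pairs[s]), s))
    sample_ids = sorted(per_run_pairs)

    rows: list[dict] = []  # consensus feature dicts
    cells: list[dict[str, PeakPair]] = []  # per-row: sample_id -> pair

    for run in run_order:
        for pair in sorted(per_run_pairs[run], key=lambda p: (p.mono12_mz, p.rt)):
            best = None
            for idx, row in enumerate(rows):
                if row["polarity"] != pair.polarity:
                    continue
                if row["carbon_count"] != pair.carbon_count:
                    continue
                dev = abs(pair.mono12_mz - row["mz12"])
                if dev > ppm_tol * 1e-6 * (row["mz12"] + pair.mono12_mz):
                    continue
                if abs(pair.rt - row["rt_sec"]) > rt_tol:
                    continue
                if best is None or dev < best[0]:
                    best = (dev, idx)
            if best is None:
                rows.append(
                    {
                        "polarity": pair.polarity,
                        "carbon_count": pair.carbon_count,
                        "mz12": pair.mono12_mz,
                        "mz13": pair.mono13_mz,
                        "rt_sec": pair.rt,
                    }
                )
                cells.append({run: pair})
            else:
                idx = best[1]
                if run in cells[idx]:
                    old = cells[idx][run]
                    keep = pair if pair.pair_score > old.pair_score else old
                    logger.debug(
                        "alignment collision in run %s at mz %.4f; kept score %.3f",
                        run, keep.mono12_mz, keep.pair_score,
                    )
                    cells[idx][run] = keep
                else:
                    cells[idx][run] = pair

    order = sorted(
        range(len(rows)),
        key=lambda i: (rows[i]["polarity"], rows[i]["mz12"], rows[i]["rt_sec"]),
    )
    row_ids = [f"M{k + 1:04d}" for k in range(len(order))]
    features = pd.DataFrame([rows[i] for i in order], index=row_ids)
    features.index.name = "row_id"
    a_s = pd.DataFrame(np.nan, index=row_ids, columns=sample_ids)
    a_i = pd.DataFrame(np.nan, index=row_ids, columns=sample_ids)
    for rid, i in zip(row_ids, order):
        for run, pair in cells[i].items():
            a_s.at[rid, run] = pair.area_sample
            a_i.at[rid, run] = pair.area_is
    return PairTable(features=features, area_sample=a_s, area_is=a_i)
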