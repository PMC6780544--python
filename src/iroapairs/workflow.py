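"""Pipeline orchestration: config, I/O, and staged execution.

The pipeline runs read -> cluster -> classify -> pair -> align -> quantify
-> impute -> statistics -> annotation -> targeted panel.  Each stage is a
function that reads its inputs from, and writes its outputs to, the
configured output directory, so the `run` entry point and the individual
CLI subcommands produce byte-identical files.

Unit conventions everywhere: retention time in seconds, m/z in Thomson,
intensities as unitless integrated areas.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .formula_id import Formula, LibraryEntry, enumerate_formulas, library_match, neutral_from_mz
from .isotope_model import LabelingScheme
from .peak_pairing import (
    CentroidPeak,
    PairTable,
    align_pairs_across_samples,
    classify_cluster_channel,
    cluster_isotopologues,
    find_peak_pairs,
)
from .quantification import (
    RatioMatrix,
    TargetEntry,
    classify_regulation,
    compute_ratios,
    impute_missing,
    log2_fold_change,
    targeted_extract,
)
from .stats import bh_qvalues, pca, random_forest_mda, top_importance, unpaired_t_test

__all__ = [
    "PipelineConfig",
    "read_peaks",
    "read_design",
    "read_library",
    "read_panel",
    "run_pipeline",
    "stage_detect",
    "stage_quantify",
    "stage_stats",
    "stage_targeted",
]

logger = logging.getLogger(__name__)

TSV_COLUMNS = ["sample_id", "polarity", "mz", "rt_sec", "intensity"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from one YAML file."""

    peaklists: list[str] = field(default_factory=list)
    design: str = ""
    out_dir: str = "iroa_out"
    polarity: str = "positive"
    ppm_tol: float = 10.0
    rt_tol: float = 6.0
    align_rt_tol: float = 6.0
    charges: tuple[int, ...] = (1,)
    p13_sample: float = 0.05
    p13_is: float = 0.95
    min_channel_score: float = 0.95
    n_min: int = 2
    n_max: int = 60
    area_mode: str = "summed"
    loq: float = 0.0
    fc_threshold: float = 1.0
    alpha: float = 0.001
    welch: bool = False
    log_transform: bool = True
    pca_scaling: str = "autoscale"
    n_trees: int = 500
    top_k: int = 40
    seed: int = 0
    library: str = ""
    panel: str = ""
    formula_tol_ppm: float = 15.0
    element_bounds: dict = field(default_factory=dict)

    @property
    def scheme(self) -> LabelingScheme:
        return LabelingScheme(self.p13_sample, self.p13_is)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "charges" in raw:
            raw["charges"] = tuple(raw["charges"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["charges"] = list(self.charges)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# readers


def read_peaks(path: str | Path, fmt: str | None = None) -> list[CentroidPeak]:
    """Read one run's centroided peaks from TSV or mzML.

    The TSV dialect is tab-separated UTF-8 with header
    ``sample_id, polarity, mz, rt_sec, intensity``.  mzML is read with
    pyteomics; profile-mode spectra are rejected because the pipeline
    operates on centroids.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mzml" if path.suffix.lower() == ".mzml" else "tsv"
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t")
        missing = set(TSV_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing TSV columns {sorted(missing)}")
        return [
            CentroidPeak(
                mz=float(r.mz),
                rt=float(r.rt_sec),
                intensity=float(r.intensity),
                sample_id=str(r.sample_id),
                polarity=str(r.polarity),
            )
            for r in frame.itertuples(index=False)
        ]
    if fmt == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown peak-list format {fmt!r}")


def _read_mzml(path: Path) -> list[CentroidPeak]:
    """Minimal centroided-mzML reader (stdlib XML + base64).

    Handles 32/64-bit float binary arrays with optional zlib compression and
    the minute/second unit variants of scan start time.  Profile-mode
    spectra are rejected.  Written in-package because no installed mzML
    parser is available to this environment's Python stack.
    """
    import base64
    import xml.etree.ElementTree as ET
    import zlib

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    peaks: list[CentroidPeak] = []
    sample_id = path.stem
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if local(elem.tag) != "spectrum":
            continue
        accessions = {}
        for cv in elem.iter():
            if local(cv.tag) == "cvParam":
                accessions.setdefault(cv.get("accession"), cv)
        if "MS:1000128" in accessions:
            raise ValueError(f"{path}: profile-mode spectrum {elem.get('id')}")
        polarity = "negative" if "MS:1000129" in accessions else "positive"
        rt_sec = 0.0
        rt_cv = accessions.get("MS:1000016")
        if rt_cv is not None:
            rt_sec = float(rt_cv.get("value"))
            if rt_cv.get("unitName", "minute") == "minute":
                rt_sec *= 60.0
        arrays = {}
        for bda in elem.iter():
            if local(bda.tag) != "binaryDataArray":
                continue
            acc = {cv.get("accession") for cv in bda.iter() if local(cv.tag) == "cvParam"}
            binary = next((c for c in bda.iter() if local(c.tag) == "binary"), None)
            if binary is None or not (binary.text or "").strip():
                continue
            raw = base64.b64decode(binary.text)
            if "MS:1000574" in acc:  # zlib
                raw = zlib.decompress(raw)
            dtype = np.float32 if "MS:1000521" in acc else np.float64
            values = np.frombuffer(raw, dtype=dtype)
            if "MS:1000514" in acc:
                arrays["mz"] = values
            elif "MS:1000515" in acc:
                arrays["intensity"] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"{path}: spectrum {elem.get('id')} lacks m/z or intensity array")
        for mz, inten in zip(arrays["mz"], arrays["intensity"]):
            if inten <= 0:
                continue
            peaks.append(
                CentroidPeak(
                    mz=float(mz), rt=rt_sec, intensity=float(inten),
                    sample_id=sample_id, polarity=polarity,
                )
            )
        elem.clear()
    return peaks


def read_design(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path)
    if not {"sample_id", "group"} <= set(frame.columns):
        raise ValueError(f"{path}: design table needs sample_id and group columns")
    bad = set(frame["group"]) - {"treatment", "control"}
    if bad:
        raise ValueError(f"{path}: unknown groups {sorted(bad)}")
    if len(set(frame["group"])) < 2:
        raise ValueError(f"{path}: design table must contain both groups")
    return frame.set_index("sample_id")["group"]


def read_library(path: str | Path) -> list[LibraryEntry]:
    """Standards library CSV: ``name, formula, rt_sec, polarity``."""
    frame = pd.read_csv(path)
    return [
        LibraryEntry(
            name=str(r["name"]),
            formula=Formula.parse(str(r["formula"])),
            rt_sec=float(r["rt_sec"]),
            polarity=str(r.get("polarity", "positive")),
        )
        for _, r in frame.iterrows()
    ]


def read_panel(path: str | Path) -> list[TargetEntry]:
    """Targeted panel CSV: ``name, formula, adducts (semicolon list), pathway_position``."""
    frame = pd.read_csv(path)
    entries = []
    for _, r in frame.iterrows():
        adducts = tuple(a.strip() for a in str(r.get("adducts", "[M+H]+")).split(";") if a.strip())
        entries.append(
            TargetEntry(
                name=str(r["name"]),
                formula=Formula.parse(str(r["formula"])),
                adducts=adducts,
                pathway_position=str(r.get("pathway_position", "")),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# on-disk intermediates


def _save_pair_table(table: PairTable, out: Path) -> None:
    table.features.to_csv(out / "pair_features.csv")
    table.area_sample.rename_axis("row_id").to_csv(out / "pair_area_sample.csv")
    table.area_is.rename_axis("row_id").to_csv(out / "pair_area_is.csv")
    table.to_long_frame().to_csv(out / "pairs.csv", index=False)


def _load_pair_table(out: Path) -> PairTable:
    features = pd.read_csv(out / "pair_features.csv", index_col="row_id")
    a_s = pd.read_csv(out / "pair_area_sample.csv", index_col="row_id")
    a_i = pd.read_csv(out / "pair_area_is.csv", index_col="row_id")
    return PairTable(features=features, area_sample=a_s, area_is=a_i)


def _save_ratio_matrix(matrix: RatioMatrix, out: Path) -> None:
    header = matrix.groups.reindex(matrix.ratios.columns)
    frame = matrix.ratios.copy()
    frame.columns = pd.MultiIndex.from_arrays(
        [frame.columns, header.values], names=["sample_id", "group"]
    )
    frame.rename_axis("row_id").to_csv(out / "ratio_matrix.csv")
    matrix.imputed_mask.rename_axis("row_id").to_csv(out / "imputed_mask.csv")


def _load_ratio_matrix(out: Path, loq: float) -> RatioMatrix:
    frame = pd.read_csv(out / "ratio_matrix.csv", header=[0, 1], index_col=0)
    groups = pd.Series(
        [g for _, g in frame.columns], index=[s for s, _ in frame.columns], name="group"
    )
    frame.columns = [s for s, _ in frame.columns]
    mask = pd.read_csv(out / "imputed_mask.csv", index_col="row_id").astype(bool)
    return RatioMatrix(ratios=frame, groups=groups, imputed_mask=mask, loq=loq)


# ---------------------------------------------------------------------------
# stages


def stage_detect(config: PipelineConfig) -> PairTable:
    """Read peak lists, detect and align peak pairs, write the pair table."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme
    per_run: dict[str, list] = {}
    counts = {}
    for path in config.peaklists:
        peaks = [p for p in read_peaks(path) if p.polarity == config.polarity]
        if not peaks:
            continue
        sid = peaks[0].sample_id
        clusters = cluster_isotopologues(
            peaks, ppm_tol=config.ppm_tol, rt_tol=config.rt_tol, charges=set(config.charges)
        )
        for cl in clusters:
            classify_cluster_channel(
                cl, scheme, min_score=config.min_channel_score, max_carbons=config.n_max
            )
        pairs = find_peak_pairs(
            clusters,
            scheme,
            ppm_tol=config.ppm_tol,
            rt_tol=config.rt_tol,
            n_range=(config.n_min, config.n_max),
            area_mode=config.area_mode,
        )
        per_run[sid] = pairs
        counts[sid] = {"peaks": len(peaks), "clusters": len(clusters), "pairs": len(pairs)}
        logger.info("%s: %d peaks -> %d clusters -> %d pairs", sid, len(peaks), len(clusters), len(pairs))
    table = align_pairs_across_samples(per_run, ppm_tol=config.ppm_tol, rt_tol=config.align_rt_tol)
    _save_pair_table(table, out)
    pd.DataFrame(counts).T.rename_axis("sample_id").to_csv(out / "stage_counts.csv")
    return table


def stage_quantify(config: PipelineConfig) -> RatioMatrix:
    """Ratios + imputation + regulation calls from the saved pair table."""
    out = Path(config.out_dir)
    table = _load_pair_table(out)
    groups = read_design(config.design)
    raw = compute_ratios(table, groups, loq=config.loq)
    matrix = impute_missing(raw)
    _save_ratio_matrix(matrix, out)
    tt = unpaired_t_test(matrix, log_transform=config.log_transform, welch=config.welch)
    calls = classify_regulation(
        matrix, tt.frame["p"], fc_threshold=config.fc_threshold, alpha=config.alpha
    )
    pd.DataFrame(
        [
            {"row_id": c.row_id, "category": c.category, "log2fc": c.log2fc, "p_value": c.p_value}
            for c in calls
        ]
    ).to_csv(out / "regulation.csv", index=False)
    return matrix


def stage_stats(config: PipelineConfig) -> dict:
    """Univariate + multivariate statistics on the saved ratio matrix."""
    out = Path(config.out_dir)
    matrix = _load_ratio_matrix(out, config.loq)
    tt = unpaired_t_test(matrix, log_transform=config.log_transform, welch=config.welch)
    fc = log2_fold_change(matrix)
    stats_frame = tt.frame.copy()
    stats_frame["q"] = bh_qvalues(tt.frame["p"])
    stats_frame["log2fc"] = fc
    stats_frame.rename_axis("row_id").to_csv(out / "stats.csv")
    pc = pca(matrix, scaling=config.pca_scaling)
    pc.scores.rename_axis("sample_id").to_csv(out / "pca_scores.csv")
    pd.DataFrame(
        {"component": pc.scores.columns, "variance_fraction": pc.variance_fraction}
    ).to_csv(out / "pca_variance.csv", index=False)
    rf = random_forest_mda(matrix, n_trees=config.n_trees, seed=config.seed)
    top = top_importance(rf, min(config.top_k, len(rf.mda)), log2fc=fc)
    top.rename_axis("row_id").to_csv(out / "rf_importance.csv")
    rf.mds_coords.rename_axis("sample_id").to_csv(out / "rf_mds.csv")
    # carbon-constrained formula annotation + library identification
    table = _load_pair_table(out)
    annotations = []
    library = read_library(config.library) if config.library else []
    for row_id, feat in table.features.iterrows():
        adduct = "[M+H]+" if feat["polarity"] == "positive" else "[M-H]-"
        neutral = neutral_from_mz(feat["mz12"], adduct)
        hits = enumerate_formulas(
            neutral,
            int(feat["carbon_count"]),
            tol_ppm=config.formula_tol_ppm,
            element_bounds=config.element_bounds or None,
        )
        ids = library_match(
            int(feat["carbon_count"]),
            float(feat["mz12"]),
            float(feat["rt_sec"]),
            str(feat["polarity"]),
            library,
            tol_ppm=config.ppm_tol,
            rt_tol=config.align_rt_tol,
        ) if library else []
        annotations.append(
            {
                "row_id": row_id,
                "best_formula": str(hits[0]) if hits else "",
                "n_formula_candidates": len(hits),
                "identified_as": ids[0]["name"] if ids else "",
                "mass_error_ppm": ids[0]["mass_error_ppm"] if ids else np.nan,
            }
        )
    pd.DataFrame(annotations).to_csv(out / "annotations.csv", index=False)
    return {"stats": stats_frame, "pca": pc, "rf": rf, "top": top}


def stage_targeted(config: PipelineConfig) -> pd.DataFrame | None:
    """Targeted pathway-panel extraction, if a panel is configured."""
    if not config.panel:
        return None
    out = Path(config.out_dir)
    table = _load_pair_table(out)
    matrix = _load_ratio_matrix(out, config.loq)
    panel = read_panel(config.panel)
    result = targeted_extract(table, panel, matrix, ppm_tol=config.ppm_tol)
    result.to_csv(out / "targeted_panel.csv", index=False)
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the in-memory result bundle.

    The config is echoed into the output directory for provenance, and a
    run log with per-stage row counts is written alongside the CSVs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_used.yaml")
    try:
        table = stage_detect(config)
        matrix = stage_quantify(config)
        stats_bundle = stage_stats(config)
        panel = stage_targeted(config)
    except Exception:
        (out / "FAILED").write_text("pipeline aborted; see log\n")
        raise
    n_pairs_cells = int(table.area_sample.notna().sum().sum())
    (out / "run_log.txt").write_text(
        "iroapairs run\n"
        f"seed: {config.seed}\n"
        f"runs: {len(config.peaklists)}\n"
        f"aligned rows: {len(table.features)}\n"
        f"filled pair cells: {n_pairs_cells}\n"
        f"quantified rows: {len(matrix.ratios)}\n"
    )
    return {"table": table, "matrix": matrix, **stats_bundle, "panel": panel}
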