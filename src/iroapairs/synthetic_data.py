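"""Synthetic dual-labeled LC/MS studies with ground truth.

Emulates the two-arm fermentation design the pipeline is built for:
treatment and control cultures grown on ~95:5 12C:13C media (n = 4 each by
default), plus one pooled ~5:95-labeled internal standard that is spiked
into every sample — so every metabolite produced in *any* arm has a heavy
partner in *every* run, including metabolites whose production the
treatment switches on or off.  Each generated run is a centroid peak list
containing both channels' binomial isotopologue envelopes with m/z noise,
RT jitter, replicate (biological) noise on the sample channel, a common
per-run injection scale factor, LOQ censoring, and unpaired artifact peaks.

What is emulated: envelope shapes, the monoisotopic gap, missingness from
censoring, on/off metabolites, artifacts.  What is not: chromatographic
peak shapes, adduct multiplicity, per-isotopologue intensity noise,
polarity switching within a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .formula_id import Formula, adduct_mz, monoisotopic_mass
from .isotope_model import DELTA_C13, LabelingScheme, carbon_isotopologue_envelope
from .peak_pairing import CentroidPeak, PairTable

__all__ = ["StudyConfig", "SyntheticStudy", "FORMULA_POOL", "generate_study", "write_fixture", "match_rows_to_truth"]

#: Plausible CHNO metabolite formulas spanning 2-36 carbons: amino acids,
#: organic acids, sugars, nucleobases/nucleosides, diketopiperazines, small
#: peptides and polyketide-sized species.  Names are only labels.
FORMULA_POOL: tuple[tuple[str, str], ...] = (
    ("glycine", "C2H5NO2"),
    ("acetate", "C2H4O2"),
    ("alanine", "C3H7NO2"),
    ("serine", "C3H7NO3"),
    ("pyruvate", "C3H4O3"),
    ("lactate", "C3H6O3"),
    ("glycerol", "C3H8O3"),
    ("threonine", "C4H9NO3"),
    ("aspartate", "C4H7NO4"),
    ("asparagine", "C4H8N2O3"),
    ("succinate", "C4H6O4"),
    ("fumarate", "C4H4O4"),
    ("malate", "C4H6O5"),
    ("uracil", "C4H4N2O2"),
    ("cytosine", "C4H5N3O"),
    ("proline", "C5H9NO2"),
    ("valine", "C5H11NO2"),
    ("glutamate", "C5H9NO4"),
    ("glutamine", "C5H10N2O3"),
    ("oxoglutarate", "C5H6O5"),
    ("ribose", "C5H10O5"),
    ("adenine", "C5H5N5"),
    ("guanine", "C5H5N5O"),
    ("thymine", "C5H6N2O2"),
    ("glutarate", "C5H8O4"),
    ("leucine", "C6H13NO2"),
    ("isoleucine", "C6H13NO2"),
    ("lysine", "C6H14N2O2"),
    ("arginine", "C6H14N4O2"),
    ("histidine", "C6H9N3O2"),
    ("glucose", "C6H12O6"),
    ("citrate", "C6H8O7"),
    ("pipecolate", "C6H11NO2"),
    ("aminobenzoate", "C7H7NO2"),
    ("benzoate", "C7H6O2"),
    ("guanidinobutanoate", "C5H11N3O2"),
    ("phenylalanine", "C9H11NO2"),
    ("tyrosine", "C9H11NO3"),
    ("hydroxyphenyllactate", "C9H10O4"),
    ("phenyllactate", "C9H10O3"),
    ("adenosine", "C10H13N5O4"),
    ("guanosine", "C10H13N5O5"),
    ("inosine", "C10H12N4O5"),
    ("uridine", "C9H12N2O6"),
    ("cytidine", "C9H13N3O5"),
    ("tryptophan", "C11H12N2O2"),
    ("ala-phe", "C12H16N2O3"),
    ("sucrose", "C12H22O11"),
    ("cyclo-pro-leu", "C11H18N2O2"),
    ("cyclo-pro-phe", "C14H16N2O2"),
    ("cyclo-leu-leu", "C12H22N2O2"),
    ("cyclo-phe-leu", "C15H20N2O2"),
    ("cyclo-phe-dehydro-leu", "C15H18N2O2"),
    ("cyclo-phe-phe", "C18H18N2O2"),
    ("cyclo-tyr-phe", "C18H18N2O3"),
    ("methyl-dkp", "C16H22N2O2"),
    ("novel-c16", "C16H24N4O7"),
    ("leu-leu-leu", "C18H35N3O4"),
    ("acyl-peptide-a", "C20H30N6O5"),
    ("tetrapeptide-a", "C22H34N6O7"),
    ("polyketide-a", "C24H38O6"),
    ("cyclopeptide-a", "C27H41N7O7"),
    ("pentapeptide-a", "C30H48N8O9"),
    ("macrolactone-a", "C32H54O8"),
    ("siderophore-a", "C33H57N9O10"),
    ("hexapeptide-a", "C36H58N10O9"),
    ("polyene-a", "C36H60O10"),
)


@dataclass
class StudyConfig:
    """Conditions of a simulated dual-label study.

    Defaults mirror the experimental design the pipeline targets: 4
    treatment and 4 control replicates, 95:5 / 5:95 labeling, metabolites of
    2-36 carbons, and modest Orbitrap-class mass error.
    """

    n_metabolites: int = 100
    n_treatment: int = 4
    n_control: int = 4
    frac_up: float = 0.10
    frac_down: float = 0.10
    frac_on: float = 0.05
    frac_off: float = 0.05
    effect_log2fc: float = 2.0
    abundance_meanlog: float = 12.0
    abundance_sdlog: float = 1.0
    replicate_cv: float = 0.10
    run_scale_cv: float = 0.05
    mass_noise_ppm: float = 3.0
    rt_jitter_sec: float = 1.0
    rt_range: tuple[float, float] = (60.0, 840.0)
    loq: float = 500.0
    artifact_rate: float = 0.10
    scheme: LabelingScheme = field(default_factory=LabelingScheme)
    carbon_range: tuple[int, int] = (2, 36)
    min_rel_intensity: float = 0.005
    polarity: str = "positive"
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.frac_up, self.frac_down, self.frac_on, self.frac_off)
        if any(f < 0 for f in fr) or sum(fr) > 1:
            raise ValueError("category fractions must be >= 0 and sum to <= 1")
        if self.n_treatment < 2 or self.n_control < 2:
            raise ValueError("need >= 2 replicates per group")


@dataclass
class SyntheticStudy:
    """Generated peak lists plus everything needed to score a pipeline run."""

    peaks: dict[str, list[CentroidPeak]]  # sample_id -> centroid peaks
    ground_truth: pd.DataFrame
    artifacts: pd.DataFrame
    groups: pd.Series  # sample_id -> treatment | control
    config: StudyConfig


def _lognormal_noise(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size if size is not None else ())
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Simulate one dual-label study; fully deterministic under config.seed.

    Per metabolite: a formula from :data:`FORMULA_POOL` (with distinct
    retention times for repeated draws), a lognormal base abundance, and a
    regulation category with deterministic counts ``round(frac * n)``.  Each
    run then receives the sample-channel envelope (group mean x replicate
    noise), the IS-channel envelope at the pooled level — the average of the
    two group means, identical in every run because the standard is one
    pooled mixture — a common injection scale factor, m/z noise, RT jitter,
    LOQ censoring, and singleton artifact peaks.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_metabolites
    pool = [
        (name, Formula.parse(f))
        for name, f in FORMULA_POOL
        if config.carbon_range[0] <= Formula.parse(f).C <= config.carbon_range[1]
    ]

    # formulas + retention times; same-formula duplicates pushed >= 30 s apart
    choices = rng.integers(0, len(pool), size=n)
    rts: list[float] = []
    rt_by_formula: dict[str, list[float]] = {}
    lo, hi = config.rt_range
    for idx in choices:
        key = str(pool[idx][1])
        taken = rt_by_formula.setdefault(key, [])
        rt = float(rng.uniform(lo, hi))
        for _ in range(200):
            if all(abs(rt - t) >= 30.0 for t in taken):
                break
            rt = float(rng.uniform(lo, hi))
        taken.append(rt)
        rts.append(rt)

    base = rng.lognormal(config.abundance_meanlog, config.abundance_sdlog, size=n)

    n_up = round(config.frac_up * n)
    n_down = round(config.frac_down * n)
    n_on = round(config.frac_on * n)
    n_off = round(config.frac_off * n)
    cats = np.array(
        ["up"] * n_up + ["down"] * n_down + ["on"] * n_on + ["off"] * n_off
        + ["unchanged"] * (n - n_up - n_down - n_on - n_off)
    )
    cats = cats[rng.permutation(n)]

    eff = config.effect_log2fc
    mean_t = np.where(cats == "up", base * 2.0**eff, base)
    mean_t = np.where(cats == "down", base * 2.0**-eff, mean_t)
    mean_t = np.where(cats == "off", 0.0, mean_t)
    mean_c = np.where(cats == "on", 0.0, base)
    mean_is = (mean_t + mean_c) / 2.0
    true_fc = np.where(
        cats == "up", eff, np.where(cats == "down", -eff, 0.0)
    ).astype(float)
    true_fc[np.isin(cats, ("on", "off"))] = np.nan

    sample_ids = [f"T{i + 1:02d}" for i in range(config.n_treatment)] + [
        f"C{i + 1:02d}" for i in range(config.n_control)
    ]
    groups = pd.Series(
        ["treatment"] * config.n_treatment + ["control"] * config.n_control,
        index=sample_ids,
        name="group",
    )

    names = [pool[i][0] for i in choices]
    formulas = [pool[i][1] for i in choices]
    carbon = np.array([f.C for f in formulas])
    neutral = np.array([monoisotopic_mass(f) for f in formulas])
    adduct = "[M+H]+" if config.polarity == "positive" else "[M-H]-"
    mz12 = np.array([adduct_mz(m, adduct) for m in neutral])

    truth = pd.DataFrame(
        {
            "metabolite_id": [f"GT{i + 1:04d}" for i in range(n)],
            "name": names,
            "formula": [str(f) for f in formulas],
            "carbon_count": carbon,
            "neutral_mass": neutral,
            "mz12": mz12,
            "rt_sec": rts,
            "category": cats,
            "true_log2fc": true_fc,
            "base_abundance": base,
            "abundance_treatment": mean_t,
            "abundance_control": mean_c,
            "abundance_is": mean_is,
        }
    ).set_index("metabolite_id")

    env_s = [carbon_isotopologue_envelope(int(c), config.scheme.p13_sample) for c in carbon]
    env_i = [carbon_isotopologue_envelope(int(c), config.scheme.p13_is) for c in carbon]

    peaks: dict[str, list[CentroidPeak]] = {}
    artifact_rows = []
    n_art = round(config.artifact_rate * n)
    for sid in sample_ids:
        run_scale = float(_lognormal_noise(rng, config.run_scale_cv))
        group_mean = mean_t if groups[sid] == "treatment" else mean_c
        run_peaks: list[CentroidPeak] = []
        for j in range(n):
            rt = rts[j] + float(rng.normal(0.0, config.rt_jitter_sec))
            amount_s = group_mean[j] * float(_lognormal_noise(rng, config.replicate_cv)) * run_scale
            amount_i = mean_is[j] * run_scale
            # the two channels share the isotopologue ladder; contributions at
            # the same 13C count coalesce into one centroid (instrument
            # resolution cannot split them)
            intens = env_s[j] * amount_s + env_i[j] * amount_i
            if intens.max() > 0:
                floor = max(config.loq, config.min_rel_intensity * intens.max())
                for k, height in enumerate(intens):
                    if height < floor:
                        continue
                    mz = (mz12[j] + k * DELTA_C13) * (
                        1.0 + rng.normal(0.0, config.mass_noise_ppm) * 1e-6
                    )
                    run_peaks.append(
                        CentroidPeak(
                            mz=mz,
                            rt=max(rt, 0.0),
                            intensity=float(height),
                            sample_id=sid,
                            polarity=config.polarity,
                        )
                    )
        for _ in range(n_art):
            a_int = float(rng.lognormal(config.abundance_meanlog, config.abundance_sdlog))
            if a_int < config.loq:
                continue
            a_mz = float(rng.uniform(80.0, 900.0))
            a_rt = float(rng.uniform(lo, hi))
            run_peaks.append(
                CentroidPeak(
                    mz=a_mz, rt=a_rt, intensity=a_int, sample_id=sid, polarity=config.polarity
                )
            )
            artifact_rows.append(
                {"sample_id": sid, "mz": a_mz, "rt_sec": a_rt, "intensity": a_int}
            )
        run_peaks.sort(key=lambda p: (p.mz, p.rt))
        peaks[sid] = run_peaks

    artifacts = pd.DataFrame(artifact_rows, columns=["sample_id", "mz", "rt_sec", "intensity"])
    return SyntheticStudy(
        peaks=peaks, ground_truth=truth, artifacts=artifacts, groups=groups, config=config
    )


def write_fixture(study: SyntheticStudy, path: str | Path) -> list[Path]:
    """Write a study to disk: one TSV peak list per run, ground truth CSV,
    design CSV, and the config echoed as YAML.  Returns the written paths."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for sid, run_peaks in study.peaks.items():
        f = path / f"{sid}.tsv"
        frame = pd.DataFrame(
            {
                "sample_id": [p.sample_id for p in run_peaks],
                "polarity": [p.polarity for p in run_peaks],
                "mz": [p.mz for p in run_peaks],
                "rt_sec": [p.rt for p in run_peaks],
                "intensity": [p.intensity for p in run_peaks],
            }
        )
        frame.to_csv(f, sep="\t", index=False)
        written.append(f)
    gt = path / "ground_truth.csv"
    study.ground_truth.to_csv(gt)
    written.append(gt)
    design = path / "design.csv"
    study.groups.rename_axis("sample_id").to_csv(design)
    written.append(design)
    cfg = path / "config.yaml"
    payload = asdict(study.config)
    payload["scheme"] = {"p13_sample": study.config.scheme.p13_sample, "p13_is": study.config.scheme.p13_is}
    cfg.write_text(yaml.safe_dump(payload, sort_keys=True))
    written.append(cfg)
    return written


def match_rows_to_truth(
    table: PairTable,
    truth: pd.DataFrame,
    ppm_tol: float = 10.0,
    rt_tol: float = 10.0,
) -> pd.Series:
    """Assign each aligned row to a ground-truth metabolite (or None).

    A row matches a true metabolite when m/z agrees within ``ppm_tol``, RT
    within ``rt_tol`` seconds, closest m/z first.  Rows matching nothing are
    spurious — with artifacts injected, any non-None leak would break the
    artifact-exclusion guarantee.  Carbon-count agreement is deliberately
    not required here, so that carbon-count errors remain visible.
    """
    out = {}
    for row_id, feat in table.features.iterrows():
        best = None
        for mid, t in truth.iterrows():
            dev = abs(feat["mz12"] - t["mz12"])
            if dev > ppm_tol * 1e-6 * t["mz12"]:
                continue
            if abs(feat["rt_sec"] - t["rt_sec"]) > rt_tol:
                continue
            if best is None or dev < best[0]:
                best = (dev, mid)
        out[row_id] = None if best is None else best[1]
    return pd.Series(out, name="metabolite_id")
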