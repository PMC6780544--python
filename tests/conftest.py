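"""Shared fixtures: synthetic studies, detection results, matrix builders."""

from __future__ import annotations

import base64
import struct

import numpy as np
import pandas as pd
import pytest

from iroapairs import (
    StudyConfig,
    align_pairs_across_samples,
    classify_cluster_channel,
    cluster_isotopologues,
    find_peak_pairs,
    generate_study,
)
from iroapairs.quantification import RatioMatrix

SAMPLES = ["T01", "T02", "T03", "T04", "C01", "C02", "C03", "C04"]
GROUPS = pd.Series(["treatment"] * 4 + ["control"] * 4, index=SAMPLES, name="group")


def make_ratio_matrix(values: np.ndarray, index=None, mask: np.ndarray | None = None) -> RatioMatrix:
    """RatioMatrix from a metabolites x 8 array of ratios (no missing cells
    unless a mask is given)."""
    values = np.asarray(values, dtype=float)
    if index is None:
        index = [f"M{i + 1:04d}" for i in range(values.shape[0])]
    ratios = pd.DataFrame(values, index=index, columns=SAMPLES)
    if mask is None:
        mask_df = pd.DataFrame(False, index=index, columns=SAMPLES)
    else:
        mask_df = pd.DataFrame(np.asarray(mask, dtype=bool), index=index, columns=SAMPLES)
    return RatioMatrix(ratios=ratios, groups=GROUPS, imputed_mask=mask_df, loq=0.0)


def detect_study(study):
    """Run the detection stages over every run of a synthetic study."""
    per_run = {}
    for sid, peaks in study.peaks.items():
        clusters = cluster_isotopologues(peaks)
        for cl in clusters:
            classify_cluster_channel(cl)
        per_run[sid] = find_peak_pairs(clusters)
    return per_run, align_pairs_across_samples(per_run)


@pytest.fixture(scope="session")
def artifact_study():
    """200-metabolite study with a high unpaired-artifact load, plus its
    detection results — shared by the artifact-exclusion and recovery checks."""
    config = StudyConfig(n_metabolites=200, artifact_rate=0.3, seed=1)
    study = generate_study(config)
    per_run, table = detect_study(study)
    return study, per_run, table


def _encode_doubles(values) -> str:
    raw = struct.pack("<" + "d" * len(values), *values)
    return base64.b64encode(raw).decode()


def write_mzml(path, scans, centroided: bool = True) -> None:
    """Write a minimal centroided mzML file readable by pyteomics.

    ``scans`` is a list of (rt_minutes, mz_array, intensity_array).  This is
    a synthetic hand-rolled writer used only to exercise the mzML reading
    path in tests.
    """
    mode_cv = (
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
        if centroided
        else '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>'
    )
    spectra = []
    for i, (rt_min, mzs, intens) in enumerate(scans):
        mz64, in64 = _encode_doubles(mzs), _encode_doubles(intens)
        spectra.append(f"""
      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mzs)}">
        {mode_cv}
        <cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_min}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(in64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{in64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    body = "".join(spectra)
    path.write_text(f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="run1">
    <spectrumList count="{len(scans)}">{body}
    </spectrumList>
  </run>
</mzML>
""")
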