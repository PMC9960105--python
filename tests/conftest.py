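"""Shared fixtures: small synthetic cohorts and a minimal mzML writer."""

from __future__ import annotations

import base64

import numpy as np
import pytest

from maldi_profiler import (CohortConfig, PeakMatrix, PeakDefinition,
                            PeakSpec, generate_cohort)


def write_minimal_mzml(path, spectra, centroided=False) -> None:
    """Write a minimal but valid mzML 1.1 document.

    ``spectra`` is a list of (mz_array, intensity_array) pairs; arrays are
    encoded as uncompressed little-endian 64-bit floats.
    """

    def b64(arr):
        return base64.b64encode(
            np.asarray(arr, dtype="<f8").tobytes()).decode()

    mode_acc = ("MS:1000127", "centroid spectrum") if centroided else \
               ("MS:1000128", "profile spectrum")
    parts = []
    for i, (mz, inten) in enumerate(spectra):
        bmz, bint = b64(mz), b64(inten)
        parts.append(f"""   <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <cvParam cvRef="MS" accession="{mode_acc[0]}" name="{mode_acc[1]}" value=""/>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{len(bmz)}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
      <binary>{bmz}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{len(bint)}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
      <binary>{bint}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
""")
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        ' <run id="run1">\n'
        f'  <spectrumList count="{len(spectra)}">\n'
        + "".join(parts) +
        "  </spectrumList>\n </run>\n</mzML>\n"
    )
    with open(path, "w") as fh:
        fh.write(doc)


def quick_cohort_config(fluid="gcf", **overrides) -> CohortConfig:
    """A narrow-window, low-cost cohort used where full-range realism is not
    the point of the test."""
    panel = [
        PeakSpec(3371.0, 40.0, {"foa": 2.0, "in": 2.0}, name="d1"),
        PeakSpec(3442.0, 80.0, {"foa": 2.0, "in": 2.0}, name="d2"),
        PeakSpec(3486.0, 26.0, {"foa": 2.0, "in": 2.0}, name="d3"),
        PeakSpec(3250.0, 30.0, name="n1"),
        PeakSpec(3600.0, 20.0, name="n2"),
    ]
    base = dict(fluid=fluid, n_per_class=15, mz_range=(3100.0, 3800.0),
                panel=panel, baseline_amplitude=10.0, baseline_decay=500.0,
                noise_sd=0.3, seed=7)
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def quick_cohort():
    """45-spectrum narrow-window cohort plus manifest (session-cached)."""
    return generate_cohort(quick_cohort_config())


@pytest.fixture(scope="session")
def default_gcf_matrix():
    """Peak matrix of the full default GCF study (45 spectra, m/z
    2000-20,000), built once per session through the whole chain."""
    from maldi_profiler import (build_peak_matrix, estimate_noise,
                                pick_peaks, preprocess_set,
                                total_average_spectrum)

    cohort, manifest = generate_cohort(CohortConfig(fluid="gcf", seed=17))
    pre = preprocess_set(cohort,
                         reference_peaks=sorted(manifest["centroid_mz"]))
    avg = total_average_spectrum(pre)
    peaks = pick_peaks(avg, estimate_noise(avg), 4.0, 300.0)
    return build_peak_matrix(pre, peaks)


def planted_matrix(n_per_class=15, n_noise_peaks=30, n_informative=1,
                   separation=3.0, cv=0.2, seed=0,
                   pattern="treated") -> PeakMatrix:
    """A peak matrix with planted differential columns among pure noise.

    ``pattern="treated"``: informative columns have class means
    1 : separation : separation for (control, foa, in).
    ``pattern="complementary"``: informative column j is elevated in foa
    (j even) or in (j odd) only, so the classes are separable only by
    combining several columns.  All columns carry lognormal scatter of the
    given CV.
    """
    rng = np.random.default_rng(seed)
    labels = (["control"] * n_per_class + ["foa"] * n_per_class +
              ["in"] * n_per_class)
    n = len(labels)
    p = n_informative + n_noise_peaks
    sigma = np.sqrt(np.log1p(cv * cv))
    values = np.empty((n, p))
    for j in range(p):
        base = rng.uniform(0.5, 2.0)
        for i, lab in enumerate(labels):
            mean = base
            if j < n_informative:
                if pattern == "treated" and lab != "control":
                    mean = base * separation
                elif pattern == "complementary" and \
                        lab == ("foa" if j % 2 == 0 else "in"):
                    mean = base * separation
            values[i, j] = mean * rng.lognormal(-0.5 * sigma ** 2, sigma)
    peaks = [PeakDefinition(2000.0 + 10.0 * j, 1995.0 + 10.0 * j,
                            2005.0 + 10.0 * j, snr_at_pick=10.0, index=j + 1)
             for j in range(p)]
    return PeakMatrix(values=values, peaks=peaks,
                      sample_ids=[f"s{i}" for i in range(n)], labels=labels)
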