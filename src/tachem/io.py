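"""CSV readers/writers for the spectral containers.

All files are plain CSV with an optional comment header of ``#`` lines
(tool version, command line, seed, timestamp) and full-precision floats
(%.15g), so a write/read round trip is lossless to 15 significant
digits.  Layouts:

* spectral matrix: first column ``wavelength_nm``, one column per sample
  (header row = sample ids); sidecar metadata CSV keyed by sample id
  with columns ``ph``, ``m_total``, ``ta_total_g_l``;
* EEM set: one CSV per sample (first column ``emission_nm``, columns =
  excitation nm) plus a manifest CSV ``sample_id,file,ph,composition``;
* Job series: columns ``molar_fraction,absorbance``.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EEMTensor, JobsSeries, SpectralMatrix
from .errors import ConfigurationError

FLOAT_FMT = "%.15g"


def header_lines(command: str = "", seed=None) -> list[str]:
    from . import __version__

    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    lines = [f"# tachem {__version__}"]
    if command:
        lines.append(f"# command: {command}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append(f"# timestamp: {stamp}")
    return lines


def _write_csv(df: pd.DataFrame, path, header: list[str] | None, index: bool) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header or []:
            fh.write(line + "\n")
        df.to_csv(fh, float_format=FLOAT_FMT, index=index)


def write_spectral_matrix(
    sm: SpectralMatrix, matrix_path, meta_path, header: list[str] | None = None
) -> None:
    df = pd.DataFrame(
        sm.absorbance.T, columns=sm.sample_meta.index, copy=True
    )
    df.insert(0, "wavelength_nm", sm.wavelengths)
    _write_csv(df, matrix_path, header, index=False)
    _write_csv(sm.sample_meta, meta_path, header, index=True)


def read_spectral_matrix(matrix_path, meta_path) -> SpectralMatrix:
    df = pd.read_csv(matrix_path, comment="#")
    if df.columns[0] != "wavelength_nm":
        raise ConfigurationError("first column must be 'wavelength_nm'")
    meta = pd.read_csv(meta_path, comment="#", index_col=0)
    meta.index = meta.index.astype(str)
    matrix_ids = [str(c) for c in df.columns[1:]]
    orphans_meta = sorted(set(meta.index) - set(matrix_ids))
    orphans_matrix = sorted(set(matrix_ids) - set(meta.index))
    if orphans_meta or orphans_matrix:
        raise ConfigurationError(
            f"sample id mismatch; only in meta: {orphans_meta}, "
            f"only in matrix: {orphans_matrix}"
        )
    absorbance = df[list(meta.index)].to_numpy(dtype=float).T  # meta order
    return SpectralMatrix(df["wavelength_nm"].to_numpy(dtype=float), absorbance, meta)


def write_eem_set(
    eem: EEMTensor, out_dir, prefix: str = "eem", header: list[str] | None = None
) -> Path:
    """Write per-sample CSVs and a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(eem.sample_meta.index):
        slab = eem.intensities[i].copy()
        slab[eem.mask[i]] = np.nan  # masked cells round-trip as blanks
        df = pd.DataFrame(slab, columns=[f"{x:g}" for x in eem.excitation])
        df.insert(0, "emission_nm", eem.emission)
        fname = f"{prefix}_{sid}.csv"
        _write_csv(df, out_dir / fname, header, index=False)
        rows.append(
            {
                "sample_id": sid,
                "file": fname,
                "ph": eem.sample_meta.loc[sid, "ph"],
                "composition": eem.sample_meta.loc[sid, "composition"],
            }
        )
    manifest = out_dir / f"{prefix}_manifest.csv"
    _write_csv(pd.DataFrame(rows), manifest, header, index=False)
    return manifest


def read_eem_set(manifest_path) -> EEMTensor:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, comment="#", dtype={"sample_id": str})
    base = manifest_path.parent
    slabs, em_grid, ex_grid = [], None, None
    for _, row in manifest.iterrows():
        df = pd.read_csv(base / row["file"], comment="#")
        em = df["emission_nm"].to_numpy(dtype=float)
        ex = np.array([float(c) for c in df.columns[1:]])
        if em_grid is None:
            em_grid, ex_grid, first = em, ex, row["file"]
        elif not (np.array_equal(em, em_grid) and np.array_equal(ex, ex_grid)):
            raise ConfigurationError(
                f"grid mismatch between {first} and {row['file']}"
            )
        slabs.append(df.iloc[:, 1:].to_numpy(dtype=float))
    data = np.stack(slabs)
    mask = np.isnan(data)
    data = np.nan_to_num(data)
    meta = manifest.set_index("sample_id")[["ph", "composition"]]
    return EEMTensor(data, em_grid, ex_grid, meta, mask=mask)


def write_jobs_series(series: JobsSeries, path, header: list[str] | None = None) -> None:
    df = pd.DataFrame(
        {
            "molar_fraction": series.molar_fraction_metal,
            "absorbance": series.absorbance,
        }
    )
    hdr = list(header or [])
    hdr.append(f"# total_conc_mol_l: {series.total_conc:.15g}")
    hdr.append(f"# wavelength_nm: {series.wavelength:.15g}")
    _write_csv(df, path, hdr, index=False)


def read_jobs_series(path) -> JobsSeries:
    total, wavelength = np.nan, np.nan
    for line in Path(path).read_text().splitlines():
        if line.startswith("# total_conc_mol_l:"):
            total = float(line.split(":", 1)[1])
        elif line.startswith("# wavelength_nm:"):
            wavelength = float(line.split(":", 1)[1])
        elif not line.startswith("#"):
            break
    df = pd.read_csv(path, comment="#")
    return JobsSeries(
        df["molar_fraction"].to_numpy(dtype=float),
        df["absorbance"].to_numpy(dtype=float),
        total,
        wavelength,
    )
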