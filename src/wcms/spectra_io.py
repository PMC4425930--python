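"""Reading and writing spectra and tabular artifacts.

Spectra travel as mzXML (one profile scan per spot, the export dialect of the
Shimadzu Launchpad path); experimental factors travel in a sample-sheet CSV
because mzXML has no standard slots for them.  Reading accepts 32/64-bit,
optionally zlib-compressed peak arrays; writing emits 32-bit network-order
uncompressed arrays for maximal interoperability.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from typing import Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mzxml as _pymzxml

from .spectrum import RawSpectrum, SpectrumMeta

__all__ = [
    "MzXMLError",
    "MalformedMzXMLError",
    "EmptyMzXMLError",
    "UnsupportedEncodingError",
    "SampleSheetError",
    "read_mzxml",
    "write_mzxml",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_experiment",
    "read_experiment",
]

_NS = "http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"


class MzXMLError(ValueError):
    """Base class for mzXML I/O failures."""


class MalformedMzXMLError(MzXMLError):
    """File is not well-formed mzXML."""


class EmptyMzXMLError(MzXMLError):
    """File contains no scans."""


class UnsupportedEncodingError(MzXMLError):
    """Peak arrays use an encoding this reader does not support."""


class SampleSheetError(ValueError):
    """Sample sheet fails validation."""


def read_mzxml(path: str | Path) -> list[RawSpectrum]:
    """Read all scans of an mzXML file as :class:`RawSpectrum` objects.

    Scan order is preserved; within each scan m/z is sorted ascending if the
    file is not.  Metadata carries the source path and scan id only — factor
    assignment comes from the sample sheet.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[RawSpectrum] = []
    try:
        with _pymzxml.read(str(path)) as reader:
            for scan in reader:
                mz = np.asarray(scan["m/z array"], dtype=float)
                inten = np.asarray(scan["intensity array"], dtype=float)
                if mz.size > 1 and np.any(np.diff(mz) <= 0):
                    order = np.argsort(mz, kind="stable")
                    mz, inten = mz[order], inten[order]
                meta = SpectrumMeta(
                    sample_id=path.stem, source=f"{path}#scan={scan.get('num', '')}"
                )
                spectra.append(RawSpectrum(mz, np.clip(inten, 0.0, None), meta))
    except etree.XMLSyntaxError as exc:
        raise MalformedMzXMLError(f"{path}: not well-formed XML ({exc})") from exc
    except (KeyError, struct.error, zlib.error, base64.binascii.Error) as exc:
        raise UnsupportedEncodingError(f"{path}: cannot decode peak data ({exc})") from exc
    if not spectra:
        raise EmptyMzXMLError(f"{path}: mzXML file contains no scans")
    return spectra


def _encode_peaks(mz: np.ndarray, intensity: np.ndarray) -> str:
    interleaved = np.empty(2 * mz.size, dtype=">f4")
    interleaved[0::2] = mz.astype(">f4")
    interleaved[1::2] = intensity.astype(">f4")
    return base64.b64encode(interleaved.tobytes()).decode("ascii")


def write_mzxml(spectra: Sequence[RawSpectrum], path: str | Path) -> Path:
    """Write spectra as one mzXML file (one scan per spectrum).

    Peak arrays are 32-bit network byte order, uncompressed, m/z-intensity
    interleaved.  Output is byte-deterministic (no timestamps).
    """
    spectra = list(spectra)
    if not spectra:
        raise MzXMLError("mzXML requires at least one scan")
    path = Path(path)
    parts = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>\n'
        f'<mzXML xmlns="{_NS}">\n'
        f' <msRun scanCount="{len(spectra)}">\n'
    ]
    for i, s in enumerate(spectra, start=1):
        if len(s) == 0:
            raise MzXMLError(f"scan {i} is empty")
        lo, hi = float(s.mz[0]), float(s.mz[-1])
        parts.append(
            f'  <scan num="{i}" msLevel="1" peaksCount="{len(s)}"'
            f' polarity="+" scanType="Full" centroided="0"'
            f' lowMz="{lo:.6f}" highMz="{hi:.6f}"'
            f' basePeakIntensity="{float(s.intensity.max()):.6f}">\n'
            f'   <peaks precision="32" byteOrder="network"'
            f' contentType="m/z-int" compressionType="none" compressedLen="0">'
            f"{escape(_encode_peaks(s.mz, s.intensity))}</peaks>\n"
            "  </scan>\n"
        )
    parts.append(" </msRun>\n</mzXML>\n")
    path.write_text("".join(parts), encoding="ascii")
    return path


# ---------------------------------------------------------------------------
# sample sheet

SHEET_COLUMNS = ["file", "donor", "population", "condition", "replicate"]


def read_sample_sheet(
    path: str | Path,
    populations: Sequence[str] | None = None,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read and validate the spectrum-to-factor assignment CSV.

    When declared level sets are given, unknown population/condition labels
    are rejected; otherwise the observed labels define the levels.  Replicate
    indices must run 1..n within each (donor, population, condition).
    """
    sheet = pd.read_csv(path, dtype={"donor": str})
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise SampleSheetError(f"sample sheet missing columns: {missing}")
    sheet = sheet[SHEET_COLUMNS].copy()
    sheet["replicate"] = sheet["replicate"].astype(int)
    if sheet["file"].duplicated().any():
        dups = sheet.loc[sheet["file"].duplicated(), "file"].tolist()
        raise SampleSheetError(f"duplicate file entries: {dups}")
    for col, levels in (("population", populations), ("condition", conditions)):
        if levels is not None:
            unknown = sorted(set(sheet[col]) - set(levels))
            if unknown:
                raise SampleSheetError(f"unknown {col} labels: {unknown}")
    for key, grp in sheet.groupby(["donor", "population", "condition"]):
        reps = sorted(grp["replicate"])
        if reps != list(range(1, len(reps) + 1)):
            raise SampleSheetError(
                f"replicates of {key} are {reps}, expected 1..{len(reps)}"
            )
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sheet[SHEET_COLUMNS].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# experiment-level convenience (simulate <-> disk round trip)


def write_experiment(spectra, truth, out_dir: str | Path) -> Path:
    """Write one mzXML per spot plus sheet.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in spectra:
        fname = f"{s.meta.sample_id}.mzXML"
        write_mzxml([s], out / fname)
        rows.append(
            {
                "file": fname,
                "donor": s.meta.donor,
                "population": s.meta.population,
                "condition": s.meta.condition,
                "replicate": s.meta.replicate,
            }
        )
    pd.DataFrame(rows).to_csv(out / "sheet.csv", index=False)
    if truth is not None:
        (out / "truth.json").write_text(truth.to_json())
    return out


def read_experiment(in_dir: str | Path, sheet_name: str = "sheet.csv"):
    """Read spectra listed in a sample sheet, attaching factor metadata."""
    in_dir = Path(in_dir)
    sheet = read_sample_sheet(in_dir / sheet_name)
    spectra: list[RawSpectrum] = []
    for row in sheet.itertuples(index=False):
        for s in read_mzxml(in_dir / row.file):
            meta = SpectrumMeta(
                sample_id=Path(row.file).stem,
                donor=str(row.donor),
                population=row.population,
                condition=row.condition,
                replicate=int(row.replicate),
                source=str(in_dir / row.file),
            )
            spectra.append(RawSpectrum(s.mz, s.intensity, meta))
    return spectra, sheet
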