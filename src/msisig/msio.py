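"""Reading and writing MSI data and the pipeline's tabular artifacts.

In-memory containers for mass spectrometry imaging data: :class:`Spectrum`
(one pixel's centroided or profile m/z–intensity arrays), :class:`MSIDataset`
(spectra on a coordinate grid plus region-of-interest masks and per-ROI
prognostic-feature labels), and :class:`AcquisitionMetadata`.

imzML 1.1 is the on-disk dialect, via pyimzml.  Processed mode (one m/z axis
per pixel, as MALDI-TOF exports) is native; continuous-mode files are read
into the same container.  Pixel coordinates are 1-based throughout, as in the
imzML standard; conversion to 0-based array indices happens only where pixel
images are rasterized.

Tabular artifacts are plain TSV/CSV: ROI masks as ``roi,x,y`` CSV, labels and
LC-MS/MS reference peptide lists as TSV, and protein-assignment reports laid
out like the published results table (MSI m/z, AUC, reference mass, signed
deviation, protein).  Numeric parsing accepts decimal commas, which appear in
published tables, and normalizes them to decimal points.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

from .annotate import PeptideMatch, ProteinAssignment, ReferencePeptide

__all__ = [
    "AcquisitionMetadata",
    "Spectrum",
    "MSIDataset",
    "read_imzml",
    "write_imzml",
    "write_results_table",
    "read_results_table",
    "write_reference_list",
    "read_reference_list",
    "write_roi_masks",
    "read_roi_masks",
    "write_labels",
    "read_labels",
]

#: Results-table layout: the five published columns plus a trailing feature tag.
RESULTS_COLUMNS = ("msi_mz", "auc", "ref_mass", "delta", "protein", "feature")


def parse_number(text: str) -> float:
    """Parse a decimal number, accepting decimal commas and unicode minus."""
    return float(str(text).strip().replace("−", "-").replace(",", "."))


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Instrument settings carried as metadata; no computation depends on them."""

    laser_shots: int = 500
    sampling_rate_gs: float = 1.25
    raster_um: float = 50.0
    mz_min: float = 800.0
    mz_max: float = 3200.0

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValueError(f"mz_min must be < mz_max, got ({self.mz_min}, {self.mz_max})")


@dataclass
class Spectrum:
    """One pixel's spectrum: parallel m/z and intensity arrays plus its (x, y) coord."""

    mz: np.ndarray
    intensity: np.ndarray
    coord: tuple[int, int]

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise ValueError(
                f"pixel {tuple(self.coord)}: mz length {len(self.mz)} != "
                f"intensity length {len(self.intensity)}"
            )
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"pixel {tuple(self.coord)}: m/z axis not strictly increasing")
        if len(self.intensity) and float(self.intensity.min()) < 0:
            raise ValueError(f"pixel {tuple(self.coord)}: negative intensity")
        self.coord = (int(self.coord[0]), int(self.coord[1]))

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class MSIDataset:
    """Spectra on a pixel grid with ROI masks and per-ROI feature labels.

    ``rois`` maps an ROI name to the set of pixel coordinates it covers;
    ``labels`` maps an ROI name to prognostic-feature statuses, e.g.
    ``{"pL": True, "pN": False, "pV": False}``.
    """

    spectra: list[Spectrum]
    pixel_size: float = 50.0
    rois: dict[str, set[tuple[int, int]]] = field(default_factory=dict)
    labels: dict[str, dict[str, bool]] = field(default_factory=dict)
    acquisition: AcquisitionMetadata = field(default_factory=AcquisitionMetadata)

    def __post_init__(self) -> None:
        coords = [s.coord for s in self.spectra]
        seen = set(coords)
        if len(seen) != len(coords):
            raise ValueError("duplicate pixel coordinates in dataset")
        for roi, pix in self.rois.items():
            missing = set(pix) - seen
            if missing:
                raise ValueError(f"ROI {roi!r} references absent pixels: {sorted(missing)[:3]}")

    @property
    def coords(self) -> list[tuple[int, int]]:
        return [s.coord for s in self.spectra]

    def roi_of(self) -> dict[tuple[int, int], str]:
        """Coordinate → ROI name map (ROIs assumed disjoint; name order breaks ties)."""
        out: dict[tuple[int, int], str] = {}
        for roi in sorted(self.rois):
            for c in self.rois[roi]:
                out.setdefault(c, roi)
        return out

    def common_axis(self) -> np.ndarray:
        """The shared m/z axis, or raise if spectra have pixel-specific axes."""
        if not self.spectra:
            raise ValueError("empty dataset has no axis")
        axis = self.spectra[0].mz
        for s in self.spectra[1:]:
            if s.mz is not axis and not np.array_equal(s.mz, axis):
                raise ValueError("spectra do not share a common m/z axis")
        return axis

    def mean_spectrum(self) -> Spectrum:
        """Dataset-wide mean spectrum (requires a common axis)."""
        axis = self.common_axis()
        total = np.zeros_like(axis)
        for s in self.spectra:
            total += s.intensity
        return Spectrum(axis.copy(), total / len(self.spectra), (0, 0))


# ---------------------------------------------------------------------------
# imzML


def read_imzml(path: str | os.PathLike) -> MSIDataset:
    """Read an imzML/.ibd pair into an :class:`MSIDataset`.

    Spectra are returned sorted by (y, x).  Both processed and continuous
    binary modes are accepted.  A pixel whose m/z and intensity arrays differ
    in length raises a ``ValueError`` naming the pixel.
    """
    path = os.fspath(path)
    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if not os.path.exists(ibd):
        raise FileNotFoundError(f"missing binary data file: {ibd}")
    parser = ImzMLParser(path)
    spectra: list[Spectrum] = []
    for i, coord in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        x, y = int(coord[0]), int(coord[1])
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float64)
        if len(mz) != len(inten):
            raise ValueError(f"pixel ({x}, {y}): mz/intensity length mismatch")
        spectra.append(Spectrum(mz, inten, (x, y)))
    try:  # release the .ibd handle
        parser.m.close()
    except AttributeError:
        pass
    spectra.sort(key=lambda s: (s.coord[1], s.coord[0]))
    if spectra:
        mz_min = min(float(s.mz[0]) for s in spectra if len(s))
        mz_max = max(float(s.mz[-1]) for s in spectra if len(s))
    else:
        mz_min, mz_max = 0.0, 1.0
    meta = AcquisitionMetadata(mz_min=min(mz_min, mz_max - 1e-9), mz_max=mz_max)
    return MSIDataset(spectra=spectra, acquisition=meta)


def write_imzml(ds: MSIDataset, path: str | os.PathLike) -> str:
    """Write a dataset as a processed-mode imzML/.ibd pair (float64, lossless)."""
    path = os.fspath(path)
    with ImzMLWriter(
        path, mz_dtype=np.float64, intensity_dtype=np.float64, mode="processed"
    ) as writer:
        for s in ds.spectra:
            writer.addSpectrum(s.mz, s.intensity, (s.coord[0], s.coord[1], 1))
    return path


# ---------------------------------------------------------------------------
# results table (published layout)


def write_results_table(assignments: list[ProteinAssignment], path: str | os.PathLike) -> str:
    """Write protein assignments as a TSV in the published results layout.

    One row per matched peptide, peptides of one protein adjacent.  MSI m/z is
    printed to 3 decimals, masses and deviations to 4, AUC to 4.
    """
    lines = ["\t".join(RESULTS_COLUMNS)]
    for a in assignments:
        for m in a.matches:
            lines.append(
                f"{m.msi_mz:.3f}\t{m.auc:.4f}\t{m.ref.mass:.4f}\t{m.delta:.4f}"
                f"\t{a.protein}\t{a.feature or ''}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return os.fspath(path)


def read_results_table(path: str | os.PathLike) -> list[ProteinAssignment]:
    """Parse a results TSV back into protein assignments.

    Consecutive rows sharing (protein, feature) form one assignment.  Decimal
    commas are normalized; the match direction is recovered from the AUC.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    idx = {name: header.index(name) for name in header}
    assignments: list[ProteinAssignment] = []
    current_key: tuple[str, str] | None = None
    current: list[PeptideMatch] = []

    def flush() -> None:
        if current:
            protein, feat = current_key  # type: ignore[misc]
            assignments.append(
                ProteinAssignment(
                    protein=protein,
                    matches=list(current),
                    direction=current[0].direction,
                    feature=feat or None,
                )
            )

    for row in rows:
        protein = row[idx["protein"]]
        feat = row[idx["feature"]] if "feature" in idx else ""
        auc = parse_number(row[idx["auc"]])
        ref = ReferencePeptide(mass=parse_number(row[idx["ref_mass"]]), protein=protein)
        match = PeptideMatch(
            msi_mz=parse_number(row[idx["msi_mz"]]),
            ref=ref,
            delta=parse_number(row[idx["delta"]]),
            auc=auc,
            direction="up" if auc > 0.5 else "down",
            feature=feat or None,
        )
        key = (protein, feat)
        if key != current_key:
            flush()
            current_key, current = key, []
        current.append(match)
    flush()
    return assignments


# ---------------------------------------------------------------------------
# reference lists, ROI masks, labels


def write_reference_list(refs: list[ReferencePeptide], path: str | os.PathLike) -> str:
    df = pd.DataFrame(
        {
            "mass": [f"{r.mass:.4f}" for r in refs],
            "protein": [r.protein for r in refs],
            "sequence": [r.sequence or "" for r in refs],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return os.fspath(path)


def read_reference_list(path: str | os.PathLike) -> list[ReferencePeptide]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        ReferencePeptide(
            mass=parse_number(row["mass"]),
            protein=row["protein"],
            sequence=row.get("sequence") or None,
        )
        for _, row in df.iterrows()
    ]


def write_roi_masks(rois: dict[str, set[tuple[int, int]]], path: str | os.PathLike) -> str:
    rows = [
        {"roi": roi, "x": x, "y": y}
        for roi in sorted(rois)
        for (x, y) in sorted(rois[roi])
    ]
    pd.DataFrame(rows, columns=["roi", "x", "y"]).to_csv(path, index=False)
    return os.fspath(path)


def read_roi_masks(path: str | os.PathLike) -> dict[str, set[tuple[int, int]]]:
    df = pd.read_csv(path)
    out: dict[str, set[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["roi"]), set()).add((int(row["x"]), int(row["y"])))
    return out


def write_labels(labels: dict[str, dict[str, bool]], path: str | os.PathLike) -> str:
    features = sorted({f for d in labels.values() for f in d})
    rows = [
        {"roi": roi, **{f: "+" if labels[roi].get(f) else "-" for f in features}}
        for roi in sorted(labels)
    ]
    pd.DataFrame(rows, columns=["roi", *features]).to_csv(path, sep="\t", index=False)
    return os.fspath(path)


def read_labels(path: str | os.PathLike) -> dict[str, dict[str, bool]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    features = [c for c in df.columns if c != "roi"]
    return {
        str(row["roi"]): {f: str(row[f]).strip() == "+" for f in features}
        for _, row in df.iterrows()
    }
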