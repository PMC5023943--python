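"""Domain types and plain-text file I/O.

All on-disk formats are vendor-free delimited text:

* spectrum: two columns (ppm, intensity), whitespace- or comma-delimited,
  one file per sample named ``<sample_id>.txt`` in a spectra directory;
* sample metadata: delimited table with columns
  ``sample_id, animal_id, group, tissue_weight_g``;
* bucket table: tab-delimited matrix, first row bucket left edges, first
  column sample ids, with ``# key=value`` header lines carrying width,
  normalisation state, groups and tissue weights;
* endpoint table: delimited table with columns
  ``animal_id, group_arm, Scr, BUN, ALB, TIS, ICD``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUPS = ("A", "B", "C", "D")
ENDPOINTS = ("Scr", "BUN", "ALB", "TIS", "ICD")
ENDPOINT_COLUMNS = ("animal_id", "group_arm") + ENDPOINTS


@dataclass
class SpectrumRecord:
    """One sample's 1D spectrum with its group label and tissue weight.

    ``group`` follows the four-kidney convention: A = obstructed (UUO left),
    B = UUO contralateral (right), C = sham left, D = sham right. The ppm
    axis is stored ascending; descending input is reversed in lockstep with
    the intensities.
    """

    sample_id: str
    animal_id: str
    group: str
    tissue_weight: float  # grams
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"sample {self.sample_id!r}: unknown group {self.group!r}")
        if not (self.tissue_weight > 0):
            raise ValueError(f"sample {self.sample_id!r}: non-positive tissue weight")
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError(f"sample {self.sample_id!r}: ppm/intensity shape mismatch")
        if self.ppm.size < 2:
            raise ValueError(f"sample {self.sample_id!r}: need at least 2 points")
        d = np.diff(self.ppm)
        if np.all(d < 0):  # accept descending, store ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise ValueError(f"sample {self.sample_id!r}: ppm axis not strictly monotone")


@dataclass
class MetaboliteAssignment:
    """Peaks and quantification window for one metabolite.

    ``peaks`` is a list of (center ppm, relative area, multiplicity label);
    ``quant_window`` is the (low, high) ppm interval of the metabolite's
    least-overlapping signal, used for relative quantification. Windows must
    avoid the residual-water region 4.68-5.23 ppm.
    """

    name: str
    peaks: list[tuple[float, float, str]]
    quant_window: tuple[float, float]

    WATER = (4.68, 5.23)

    def __post_init__(self) -> None:
        lo, hi = self.quant_window
        if not lo < hi:
            raise ValueError(f"{self.name}: quant_window low must be < high")
        if lo < self.WATER[1] and hi > self.WATER[0]:
            raise ValueError(f"{self.name}: quant_window overlaps the water "
                             f"exclusion region {self.WATER}")


@dataclass
class BucketTable:
    """Samples x bucket-integral matrix with bucket-edge metadata.

    ``normalized`` is ``"raw"`` for plain integrals or ``"per-gram"`` after
    tissue-weight normalisation. ``tissue_weights`` (grams, per sample) is
    carried so normalisation can be applied downstream of construction.
    """

    sample_ids: list[str]
    groups: list[str]
    bucket_left_edges: np.ndarray
    bucket_width: float
    values: np.ndarray
    normalized: str = "raw"
    tissue_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bucket_left_edges = np.asarray(self.bucket_left_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) == 0:
            raise ValueError("empty table")
        if self.normalized not in ("raw", "per-gram"):
            raise ValueError(f"unknown normalization state {self.normalized!r}")
        if len(self.sample_ids) != len(self.groups):
            raise ValueError("sample_ids and groups length mismatch")
        if self.values.shape != (len(self.sample_ids), self.bucket_left_edges.size):
            raise ValueError("values shape does not match sample_ids x bucket edges")
        for g in self.groups:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
        if self.tissue_weights is not None:
            self.tissue_weights = np.asarray(self.tissue_weights, dtype=float)
            if self.tissue_weights.size != len(self.sample_ids):
                raise ValueError("tissue_weights length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.bucket_left_edges)

    def copy(self) -> "BucketTable":
        return replace(
            self,
            sample_ids=list(self.sample_ids),
            groups=list(self.groups),
            bucket_left_edges=self.bucket_left_edges.copy(),
            values=self.values.copy(),
            tissue_weights=None if self.tissue_weights is None
            else self.tissue_weights.copy(),
        )


# ---------------------------------------------------------------------------
# spectra


def _read_xy(path: str) -> tuple[np.ndarray, np.ndarray]:
    ppm, inten = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                ppm.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value in spectrum") from None
    return np.array(ppm), np.array(inten)


def read_metadata(metadata_path: str) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep=None, engine="python")
    required = {"sample_id", "animal_id", "group", "tissue_weight_g"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def read_spectra(path: str, metadata_path: str) -> list[SpectrumRecord]:
    """Read one spectrum per metadata row from a directory of xy text files.

    ``path`` is a directory holding ``<sample_id>.txt`` files. Raises if any
    metadata row lacks its spectrum file, naming the sample.
    """
    meta = read_metadata(metadata_path)
    records = []
    for _, row in meta.iterrows():
        sid = str(row["sample_id"])
        fn = os.path.join(path, f"{sid}.txt")
        if not os.path.exists(fn):
            raise FileNotFoundError(f"spectrum file missing for sample {sid!r}: {fn}")
        ppm, inten = _read_xy(fn)
        records.append(SpectrumRecord(
            sample_id=sid,
            animal_id=str(row["animal_id"]),
            group=str(row["group"]),
            tissue_weight=float(row["tissue_weight_g"]),
            ppm=ppm,
            intensity=inten,
        ))
    return records


def write_spectra(records: list[SpectrumRecord], path: str, metadata_path: str) -> None:
    """Write spectra as per-sample xy files plus a metadata table."""
    os.makedirs(path, exist_ok=True)
    rows = []
    for rec in records:
        with open(os.path.join(path, f"{rec.sample_id}.txt"), "w") as fh:
            for x, y in zip(rec.ppm, rec.intensity):
                fh.write(f"{x:.17g}\t{y:.17g}\n")
        rows.append({"sample_id": rec.sample_id, "animal_id": rec.animal_id,
                     "group": rec.group, "tissue_weight_g": rec.tissue_weight})
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bucket tables


def write_bucket_table(table: BucketTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bucket_width={table.bucket_width:.17g}\n")
        fh.write(f"# normalized={table.normalized}\n")
        fh.write("# groups=" + ",".join(table.groups) + "\n")
        if table.tissue_weights is not None:
            fh.write("# tissue_weights_g="
                     + ",".join(f"{w:.17g}" for w in table.tissue_weights) + "\n")
        fh.write("sample_id\t" + "\t".join(f"{e:.17g}" for e in table.bucket_left_edges)
                 + "\n")
        for sid, row in zip(table.sample_ids, table.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_bucket_table(path: str) -> BucketTable:
    header: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val
            else:
                rows.append(line.split("\t"))
    if not rows or rows[0][0] != "sample_id":
        raise ValueError(f"{path}: malformed bucket table header")
    edges = np.array([float(v) for v in rows[0][1:]])
    sample_ids = [r[0] for r in rows[1:]]
    if not sample_ids:
        raise ValueError("empty table")
    try:
        values = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    except ValueError:
        raise ValueError(f"{path}: non-numeric bucket value") from None
    if values.shape[1] != edges.size:
        raise ValueError(f"{path}: row length does not match bucket-edge header")
    groups = header.get("groups", "").split(",") if header.get("groups") else []
    if len(groups) != len(sample_ids):
        raise ValueError(f"{path}: group header does not match sample count")
    weights = None
    if "tissue_weights_g" in header:
        weights = np.array([float(w) for w in header["tissue_weights_g"].split(",")])
    return BucketTable(
        sample_ids=sample_ids,
        groups=groups,
        bucket_left_edges=edges,
        bucket_width=float(header["bucket_width"]),
        values=values,
        normalized=header.get("normalized", "raw"),
        tissue_weights=weights,
    )


# ---------------------------------------------------------------------------
# endpoint tables


def validate_endpoints(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an endpoint table (animal-level clinical/histology values).

    Columns: ``animal_id, group_arm (UUO|SO), Scr, BUN, ALB, TIS, ICD``.
    TIS is an ordinal 0-3 grade (fractional animal-level means allowed);
    ICD is a percent area in [0, 100].
    """
    missing = set(ENDPOINT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"endpoint table missing columns: {sorted(missing)}")
    bad_arm = set(df["group_arm"]) - {"UUO", "SO"}
    if bad_arm:
        raise ValueError(f"unknown group_arm values: {sorted(bad_arm)}")
    tis = df["TIS"].astype(float)
    if ((tis < 0) | (tis > 3)).any():
        raise ValueError("TIS outside [0, 3]")
    icd = df["ICD"].astype(float)
    if ((icd < 0) | (icd > 100)).any():
        raise ValueError("ICD outside [0, 100]")
    return df


def read_endpoints(path: str) -> pd.DataFrame:
    return validate_endpoints(pd.read_csv(path, sep=None, engine="python"))


def write_endpoints(df: pd.DataFrame, path: str) -> None:
    validate_endpoints(df).to_csv(path, sep="\t", index=False)
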