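"""Reading, writing and assembly of landmark data.

Supported interchange formats are 3D Slicer markups (``.mrk.json``), Slicer
FCSV fiducial files, and Rohlf TPS files.  Landmark homology is by *label*:
when a dataset is assembled, every configuration is reordered to a common
template label sequence, so digitization order in the files is irrelevant.

Missing landmarks are carried as a boolean mask, never as magic coordinate
values; masked rows hold NaN sentinels that must not enter arithmetic.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "LandmarkConfiguration",
    "PairingMap",
    "SpecimenMetadata",
    "LandmarkDataset",
    "read_slicer_markups",
    "read_fcsv",
    "read_tps_file",
    "write_tps",
    "assemble_dataset",
    "read_metadata_table",
]


@dataclass
class LandmarkConfiguration:
    """One specimen's labelled landmark coordinates (mm).

    ``coords`` is a ``k x D`` array, ``D`` in {2, 3}.  Rows flagged in
    ``missing_mask`` contain NaN and are excluded from all arithmetic.
    """

    specimen_id: str
    coords: np.ndarray
    labels: list[str]
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValidationError(
                f"{self.specimen_id}: coords must be k x D with D in (2, 3), "
                f"got shape {self.coords.shape}"
            )
        k = self.coords.shape[0]
        if k < 3:
            raise ValidationError(f"{self.specimen_id}: need at least 3 landmarks, got {k}")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != k:
            raise ValidationError(
                f"{self.specimen_id}: {len(self.labels)} labels for {k} landmarks"
            )
        if len(set(self.labels)) != k:
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValidationError(f"{self.specimen_id}: duplicate labels {dupes}")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.coords).all(axis=1)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (k,):
            raise ValidationError(f"{self.specimen_id}: missing_mask must have length {k}")
        # enforce the NaN sentinel on masked rows
        self.coords = self.coords.copy()
        self.coords[self.missing_mask] = np.nan
        if np.isnan(self.coords[~self.missing_mask]).any():
            raise ValidationError(
                f"{self.specimen_id}: non-finite coordinates outside missing_mask"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def reordered(self, template_labels: Sequence[str]) -> "LandmarkConfiguration":
        """Return a copy with rows permuted to ``template_labels`` order."""
        if set(template_labels) != set(self.labels):
            extra = sorted(set(self.labels) - set(template_labels))
            missing = sorted(set(template_labels) - set(self.labels))
            raise ValidationError(
                f"{self.specimen_id}: label mismatch with template "
                f"(extra={extra}, absent={missing})"
            )
        index = {l: i for i, l in enumerate(self.labels)}
        order = [index[l] for l in template_labels]
        return LandmarkConfiguration(
            specimen_id=self.specimen_id,
            coords=self.coords[order],
            labels=list(template_labels),
            missing_mask=self.missing_mask[order],
        )


@dataclass
class PairingMap:
    """Bilateral landmark structure: (left, right) pairs plus midline labels."""

    pairs: list[tuple[str, str]]
    midline: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        self.midline = [str(m) for m in self.midline]
        flat = [l for p in self.pairs for l in p] + list(self.midline)
        if len(set(flat)) != len(flat):
            dupes = sorted({l for l in flat if flat.count(l) > 1})
            raise ValidationError(f"pairing labels appear more than once: {dupes}")

    @property
    def labels(self) -> list[str]:
        return [l for p in self.pairs for l in p] + list(self.midline)

    def validate_against(self, labels: Sequence[str]) -> None:
        own, have = set(self.labels), set(labels)
        if own != have:
            raise ValidationError(
                f"pairing does not cover configuration labels "
                f"(unpaired={sorted(have - own)}, unknown={sorted(own - have)})"
            )


@dataclass
class SpecimenMetadata:
    specimen_id: str
    species: str = ""
    region: str = ""
    island: str = ""
    sex: str = ""
    replicate_of: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class LandmarkDataset:
    """Validated collection of configurations sharing one label template."""

    configurations: list[LandmarkConfiguration]
    pairing: PairingMap | None
    metadata: dict[str, SpecimenMetadata]

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def labels(self) -> list[str]:
        return self.configurations[0].labels

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def ndim(self) -> int:
        return self.configurations[0].ndim

    def coords_array(self) -> np.ndarray:
        """Stack to n x k x D.  Raises if any landmark is missing."""
        if self.total_missing:
            raise ValidationError(
                "dataset has missing landmarks; run estimate_missing first"
            )
        return np.stack([c.coords for c in self.configurations])

    @property
    def total_missing(self) -> int:
        return sum(c.n_missing for c in self.configurations)

    def missing_report(self) -> dict[str, int]:
        return {c.specimen_id: c.n_missing for c in self.configurations if c.n_missing}

    def factor_frame(self) -> pd.DataFrame:
        """Specimen factors as a DataFrame aligned with configuration order."""
        rows = []
        for c in self.configurations:
            m = self.metadata[c.specimen_id]
            rows.append(
                {
                    "specimen_id": m.specimen_id,
                    "species": m.species,
                    "region": m.region,
                    "island": m.island,
                    "sex": m.sex,
                    "replicate_of": m.replicate_of,
                }
            )
        return pd.DataFrame(rows)

    def subset(self, keep: Sequence[bool] | Sequence[int]) -> "LandmarkDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        configs = [self.configurations[i] for i in idx]
        meta = {c.specimen_id: self.metadata[c.specimen_id] for c in configs}
        return LandmarkDataset(configs, self.pairing, meta)


# ---------------------------------------------------------------------------
# readers / writers


def read_slicer_markups(path: str | Path) -> LandmarkConfiguration:
    """Read one 3D Slicer markups fiducial file (.mrk.json or .fcsv)."""
    path = Path(path)
    if path.suffix.lower() == ".fcsv":
        return read_fcsv(path)
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    try:
        markups = doc["markups"][0]
        points = markups["controlPoints"]
    except (KeyError, IndexError) as exc:
        raise ParseError(f"{path}: not a Slicer markups file ({exc!r})") from exc
    labels, coords, missing = [], [], []
    for i, pt in enumerate(points):
        labels.append(pt.get("label", f"F-{i + 1}"))
        pos = pt.get("position")
        defined = pt.get("positionStatus", "defined") == "defined"
        if pos is None or not defined or any(v is None for v in pos):
            coords.append([np.nan] * 3)
            missing.append(True)
        else:
            coords.append([float(v) for v in pos])
            missing.append(False)
    return LandmarkConfiguration(
        specimen_id=path.name.split(".")[0],
        coords=np.asarray(coords, dtype=float),
        labels=labels,
        missing_mask=np.asarray(missing),
    )


def read_fcsv(path: str | Path) -> LandmarkConfiguration:
    """Read a Slicer FCSV fiducial file; blank coordinate cells mark missing."""
    path = Path(path)
    labels, coords, missing = [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = next(csv.reader([line]))
            if len(cells) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 columns, got {len(cells)}")
            xyz = cells[1:4]
            label = cells[11] if len(cells) > 11 and cells[11] else cells[0]
            labels.append(label)
            if any(c.strip() == "" for c in xyz):
                coords.append([np.nan] * 3)
                missing.append(True)
            else:
                try:
                    coords.append([float(c) for c in xyz])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric coordinate {xyz}") from exc
                missing.append(False)
    if not labels:
        raise ParseError(f"{path}: no fiducial rows found")
    return LandmarkConfiguration(
        specimen_id=path.name.split(".")[0],
        coords=np.asarray(coords, dtype=float),
        labels=labels,
        missing_mask=np.asarray(missing),
    )


def read_tps_file(path: str | Path) -> list[LandmarkConfiguration]:
    """Read a Rohlf TPS file; one configuration per LM=/LM3= record.

    TPS files carry no landmark labels; canonical labels ``LM1..LMk`` are
    generated.  NaN coordinate rows are flagged as missing.
    """
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    k_expected: int | None = None
    ndim = 0
    rows: list[list[float]] = []
    spec_id: str | None = None
    record_line = 0

    def flush(lineno: int) -> None:
        nonlocal k_expected, rows, spec_id
        if k_expected is None:
            return
        if len(rows) != k_expected:
            raise ParseError(
                f"{path}:{record_line}: LM header says {k_expected} landmarks "
                f"but {len(rows)} coordinate rows found (at line {lineno})"
            )
        coords = np.asarray(rows, dtype=float)
        sid = spec_id if spec_id is not None else f"record_{len(configs) + 1}"
        configs.append(
            LandmarkConfiguration(
                specimen_id=sid,
                coords=coords,
                labels=[f"LM{i + 1}" for i in range(k_expected)],
            )
        )
        k_expected, rows, spec_id = None, [], None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                flush(lineno)
                record_line = lineno
                ndim = 3 if upper.startswith("LM3=") else 2
                try:
                    k_expected = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad LM header {line!r}") from exc
            elif "=" in line and not _looks_numeric(line):
                key, _, value = line.partition("=")
                if key.strip().upper() == "ID":
                    spec_id = value.strip()
            else:
                if k_expected is None:
                    raise ParseError(f"{path}:{lineno}: coordinate row before LM header")
                parts = line.split()
                if len(parts) != ndim:
                    raise ParseError(
                        f"{path}:{lineno}: expected {ndim} coordinates, got {len(parts)}"
                    )
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
    flush(lineno=-1)
    if not configs:
        raise ParseError(f"{path}: no TPS records found")
    return configs


def _looks_numeric(line: str) -> bool:
    try:
        [float(p) for p in line.split()]
        return True
    except ValueError:
        return False


def write_tps(path: str | Path, configs: Iterable[LandmarkConfiguration]) -> None:
    """Write configurations as a TPS file (labels are not preserved)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for cfg in configs:
            header = "LM3" if cfg.ndim == 3 else "LM"
            fh.write(f"{header}={cfg.k}\n")
            for row in cfg.coords:
                fh.write(" ".join("NaN" if not np.isfinite(v) else repr(float(v)) for v in row))
                fh.write("\n")
            fh.write(f"ID={cfg.specimen_id}\n")


def read_metadata_table(path: str | Path) -> pd.DataFrame:
    """Read a specimen metadata CSV (must contain a specimen_id column)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if "specimen_id" not in df.columns:
        raise ParseError(f"{path}: metadata table lacks a specimen_id column")
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValidationError(f"duplicate specimen_id values in metadata: {dupes}")
    return df


def assemble_dataset(
    configs: Sequence[LandmarkConfiguration],
    metadata: pd.DataFrame | Mapping[str, SpecimenMetadata],
    pairing: PairingMap | None = None,
    template_labels: Sequence[str] | None = None,
) -> LandmarkDataset:
    """Validate and assemble configurations into a LandmarkDataset.

    All configurations are reordered to ``template_labels`` (default: the
    label sequence of the first configuration).  Every configuration must
    have a metadata row; nothing is silently dropped.
    """
    if not configs:
        raise ValidationError("no configurations supplied")
    template = list(template_labels) if template_labels is not None else list(configs[0].labels)
    reordered = [c.reordered(template) for c in configs]
    ndims = {c.ndim for c in reordered}
    if len(ndims) != 1:
        raise ValidationError(f"mixed coordinate dimensions {sorted(ndims)}")
    ids = [c.specimen_id for c in reordered]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate specimen ids: {dupes}")

    if isinstance(metadata, pd.DataFrame):
        meta_map: dict[str, SpecimenMetadata] = {}
        for _, row in metadata.iterrows():
            rep = row.get("replicate_of", "") or None
            meta_map[row["specimen_id"]] = SpecimenMetadata(
                specimen_id=row["specimen_id"],
                species=row.get("species", ""),
                region=row.get("region", ""),
                island=row.get("island", ""),
                sex=row.get("sex", ""),
                replicate_of=rep,
            )
    else:
        meta_map = dict(metadata)
    absent = [i for i in ids if i not in meta_map]
    if absent:
        raise ValidationError(f"metadata missing for specimens: {absent}")

    if pairing is not None:
        pairing.validate_against(template)
    meta_used = {i: meta_map[i] for i in ids}
    return LandmarkDataset(reordered, pairing, meta_used)
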