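"""Plain-text readers and writers for the pipeline's interchange formats.

Everything travels as TSV: timeseries matrices (rows = timepoints, columns
headed by parcel ids), square matrices with parcel-id headers, parcel
schemes, cohort/dose tables, gradient score tables, and tidy statistics
tables, plus JSON run manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import ParcelScheme
from .synthetic import ScanTimeseries, SyntheticCohort


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# timeseries
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_timeseries(
    path,
    scheme: ParcelScheme | None = None,
    scan_id: str | None = None,
    subject: str = "unknown",
    condition: str = "control",
) -> ScanTimeseries:
    """Read a time × parcel TSV/CSV matrix with a parcel-id header row.

    If a scheme is supplied the columns are checked against it (missing or
    extra parcels are reported by id) and reordered to scheme order.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:  # pandas reports the offending line
        raise ParseError(f"{path}: {exc}") from exc
    non_numeric = [
        c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])
    ]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric column(s) {non_numeric[:5]}")
    if not np.isfinite(frame.to_numpy()).all():
        raise ParseError(f"{path}: non-finite values present")
    if scheme is not None:
        expected = list(scheme.parcel_ids)
        missing = sorted(set(expected) - set(frame.columns))
        extra = sorted(set(frame.columns) - set(expected))
        if missing or extra:
            raise ParseError(
                f"{path}: parcel mismatch (missing {missing[:5]}, extra {extra[:5]})"
            )
        frame = frame[expected]
    return ScanTimeseries(
        scan_id=scan_id or path.stem,
        subject=subject,
        condition=condition,
        data=frame.to_numpy(float),
        parcel_ids=tuple(frame.columns),
    )


def write_timeseries(scan: ScanTimeseries, path) -> None:
    pd.DataFrame(scan.data, columns=list(scan.parcel_ids)).to_csv(
        path, sep=_sep_for(path), index=False
    )


# ---------------------------------------------------------------------------
# square matrices / gradients
# ---------------------------------------------------------------------------

def write_matrix(values: np.ndarray, parcel_ids, path) -> None:
    """Square parcel × parcel matrix as TSV with id header and index."""
    pd.DataFrame(values, index=list(parcel_ids), columns=list(parcel_ids)).to_csv(
        path, sep="\t", index_label="parcel_id"
    )


def read_matrix(path) -> tuple[np.ndarray, tuple]:
    frame = pd.read_csv(path, sep="\t", index_col="parcel_id")
    return frame.to_numpy(float), tuple(frame.columns)


def write_gradients(gradients, path) -> None:
    """Gradient scores as TSV: parcel_id, g1..gK (labeled axes keep names)."""
    cols = []
    for i in range(gradients.n_components):
        label = (gradients.labels or {}).get(i)
        cols.append(label if label else f"g{i + 1}")
    frame = pd.DataFrame(gradients.scores, columns=cols)
    frame.insert(0, "parcel_id", list(gradients.parcel_ids))
    frame.to_csv(path, sep="\t", index=False)


def write_eigen_table(gradients, path) -> None:
    pd.DataFrame(
        {
            "component": np.arange(1, gradients.n_components + 1),
            "eigenvalue": gradients.eigenvalues,
            "variance_explained": gradients.variance_explained,
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortTable:
    """Scan inventory: scan id, subject, group, condition, DDE, file path.

    Invariants: every PD subject has exactly one ON and one OFF scan,
    controls have a single scan, and referenced files exist (when
    ``base_dir`` is supplied, paths are resolved against it).
    """

    table: pd.DataFrame
    base_dir: Path | None = None

    def __post_init__(self):
        required = {"scan_id", "subject", "group", "condition", "path"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParseError(f"cohort table missing columns: {sorted(missing)}")
        tab = self.table.reset_index(drop=True)
        pd_rows = tab[tab["group"] == "PD"]
        for sub, grp in pd_rows.groupby("subject"):
            conds = sorted(grp["condition"])
            if conds != ["OFF", "ON"]:
                raise ParseError(f"PD subject {sub} must have exactly ON and OFF scans")
        ctl = tab[tab["group"] == "control"]
        if ctl["subject"].duplicated().any():
            raise ParseError("control subjects must have a single scan")
        object.__setattr__(self, "table", tab)

    def resolve(self, path_value) -> Path:
        p = Path(path_value)
        return (self.base_dir / p) if (self.base_dir and not p.is_absolute()) else p

    def validate_files(self) -> None:
        for p in self.table["path"]:
            if not self.resolve(p).exists():
                raise ParseError(f"referenced timeseries file missing: {p}")

    def doses(self) -> pd.DataFrame:
        pd_rows = self.table[self.table["group"] == "PD"]
        out = pd_rows.drop_duplicates("subject")[["subject", "DDE"]].reset_index(drop=True)
        return out

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        path = Path(path)
        return cls(pd.read_csv(path, sep="\t"), base_dir=path.parent)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def write_cohort(cohort: SyntheticCohort, out_dir) -> CohortTable:
    """Write a synthetic cohort to disk (scheme, scans, cohort/dose tables)."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    cohort.scheme.to_tsv(out / "parcel_scheme.tsv")
    dose = cohort.doses.set_index("subject")["DDE"]
    rows = []
    for scan in cohort.scans:
        rel = f"timeseries/{scan.scan_id}.tsv"
        write_timeseries(scan, out / rel)
        is_pd = scan.condition in ("ON", "OFF")
        rows.append(
            {
                "scan_id": scan.scan_id,
                "subject": scan.subject,
                "group": "PD" if is_pd else "control",
                "condition": scan.condition,
                "DDE": float(dose[scan.subject]) if is_pd else np.nan,
                "path": rel,
            }
        )
    table = CohortTable(pd.DataFrame(rows), base_dir=out)
    table.to_tsv(out / "cohort.tsv")
    cohort.doses.to_csv(out / "doses.tsv", sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def file_checksum(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(path, config: dict, outputs: dict, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "software": {"name": "funcgrad", "version": __version__},
        "config": config,
        "outputs": outputs,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
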