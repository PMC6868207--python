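"""File formats, run configuration and reproducibility plumbing.

Window time series use a two-column whitespace-separated text dialect in
which lines starting with ``#`` or ``@`` are comments — a superset of
common pull-coordinate outputs (xvg-like), so real MD data can be ingested
unchanged.  Columns are (time ns, coordinate nm) unless the manifest
declares otherwise.  Profiles are 3-column TSV with a ``#`` header carrying
units and provenance; results are JSON.  SHA-256 checksums link derived
files to their inputs; every writer goes through an atomic-rename helper so
interrupted runs leave only files with a ``.partial`` suffix, never
unmarked partial output.

Coordinate convention, declared in every header: z in nm, membrane centre
at z = 0, outer leaflet at z > 0; curvature is positive when the outer
monolayer is convex.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import DEFAULT_TEMPERATURE
from .dynamics import UmbrellaWindow
from .errors import ValidationError
from .profiles import PMFProfile, Profile, ResistanceProfile

__all__ = [
    "read_window_series",
    "write_window_series",
    "read_manifest",
    "write_window_set",
    "load_window_set",
    "write_profile",
    "read_profile",
    "write_result",
    "read_result",
    "RunConfig",
    "sha256_file",
    "atomic_write",
]

CONVENTION = "z in nm, membrane centre at z=0, outer leaflet at z>0, curvature>0 = outer monolayer convex"

MANIFEST_COLUMNS = ["file", "center_nm", "force_constant_kJ_mol_nm2", "dt_ns", "temperature_K"]


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class atomic_write:
    """Context manager: write to ``<path>.partial``, rename on clean exit.

    On an exception the ``.partial`` file is left in place, so interrupted
    output is always explicitly marked.
    """

    def __init__(self, path, mode: str = "w"):
        self.path = Path(path)
        self.partial = self.path.with_name(self.path.name + ".partial")
        self.mode = mode

    def __enter__(self):
        self.fh = open(self.partial, self.mode)
        return self.fh

    def __exit__(self, exc_type, exc, tb):
        self.fh.close()
        if exc_type is None:
            os.replace(self.partial, self.path)
        return False


def _provenance(extra: dict | None = None) -> dict:
    prov = {"package": f"curvperm {__version__}", "convention": CONVENTION}
    if extra:
        prov.update(extra)
    return prov


# ---------------------------------------------------------------------------
# Window series (xvg-like dialect)
# ---------------------------------------------------------------------------

def read_window_series(path) -> tuple[np.ndarray, float]:
    """Parse a two-column time-series file; returns (samples, dt).

    Lines starting with ``#`` or ``@`` are ignored.  The time column must be
    uniform to a relative tolerance of 1e-9 (the error names the first
    offending line); fewer than 2 data lines is an error.
    """
    times, values, line_numbers = [], [], []
    with open(path, "r") as fh:
        for ln, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith("#") or s.startswith("@"):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ValidationError(f"{path}:{ln}: expected two columns, got {len(parts)}")
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValidationError(f"{path}:{ln}: non-numeric data: {s!r}") from exc
            times.append(t)
            values.append(v)
            line_numbers.append(ln)
    if len(values) < 2:
        raise ValidationError(f"{path}: need at least 2 data lines, found {len(values)}")
    times = np.asarray(times)
    dt = times[1] - times[0]
    if dt <= 0:
        raise ValidationError(f"{path}:{line_numbers[1]}: time column must increase")
    diffs = np.diff(times)
    bad = np.nonzero(np.abs(diffs - dt) > 1e-9 * max(abs(dt), 1.0))[0]
    if bad.size:
        raise ValidationError(
            f"{path}:{line_numbers[int(bad[0]) + 1]}: non-uniform time step "
            f"({diffs[bad[0]]:.12g} vs {dt:.12g})"
        )
    return np.asarray(values, dtype=float), float(dt)


def write_window_series(path, samples: np.ndarray, dt: float,
                        header: dict | None = None) -> None:
    """Write a window series in the xvg-like dialect (12 significant digits)."""
    samples = np.asarray(samples, dtype=float)
    with atomic_write(path) as fh:
        for k, v in _provenance(header).items():
            fh.write(f"# {k} = {v}\n")
        fh.write('@ title "umbrella window reaction-coordinate series"\n')
        fh.write('@ xaxis label "time (ns)"\n')
        fh.write('@ yaxis label "z (nm)"\n')
        for i, v in enumerate(samples):
            fh.write(f"{i * dt:.12g} {v:.12g}\n")


# ---------------------------------------------------------------------------
# Manifests and window sets
# ---------------------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    """Read a window manifest TSV; validates columns, unique centres, files."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MANIFEST_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: manifest lacks columns {missing}")
    if "temperature_K" not in df.columns:
        df["temperature_K"] = DEFAULT_TEMPERATURE
    if df["center_nm"].duplicated().any():
        dups = df.loc[df["center_nm"].duplicated(), "center_nm"].tolist()
        raise ValidationError(f"{path}: duplicate window centres {dups}")
    base = Path(path).parent
    for f in df["file"]:
        fp = base / f
        if not fp.is_file():
            raise ValidationError(f"{path}: window file {fp} is not readable")
    return df


def write_window_set(windows: list[UmbrellaWindow], out_dir,
                     header: dict | None = None) -> Path:
    """Write all windows plus a manifest under ``out_dir``; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        name = f"window_{i:03d}.xvg"
        write_window_series(out_dir / name, w.samples, w.dt,
                            header={**(header or {}),
                                    "center_nm": w.center,
                                    "force_constant_kJ_mol_nm2": w.force_constant,
                                    "seed": w.seed})
        rows.append({"file": name, "center_nm": w.center,
                     "force_constant_kJ_mol_nm2": w.force_constant,
                     "dt_ns": w.dt, "temperature_K": w.temperature})
    manifest = out_dir / "manifest.tsv"
    with atomic_write(manifest) as fh:
        for k, v in _provenance(header).items():
            fh.write(f"# {k} = {v}\n")
        pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(fh, sep="\t", index=False)
    return manifest


def load_window_set(manifest_path) -> list[UmbrellaWindow]:
    """Load a full window set from a manifest (units per the declared dialect)."""
    df = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    windows = []
    for _, row in df.iterrows():
        samples, dt = read_window_series(base / row["file"])
        if abs(dt - row["dt_ns"]) > 1e-9 * max(dt, 1.0):
            raise ValidationError(
                f"{row['file']}: file dt {dt:g} disagrees with manifest dt {row['dt_ns']:g}"
            )
        windows.append(UmbrellaWindow(
            center=float(row["center_nm"]),
            force_constant=float(row["force_constant_kJ_mol_nm2"]),
            dt=dt, samples=samples, temperature=float(row["temperature_K"]),
        ))
    return windows


# ---------------------------------------------------------------------------
# Profiles and results
# ---------------------------------------------------------------------------

_PROFILE_CLASSES = {"pmf": PMFProfile, "resistance": ResistanceProfile}


def write_profile(path, profile: Profile, header: dict | None = None) -> None:
    """Write a profile as 3-column TSV (z, value, sigma) with a ``#`` header."""
    meta = {k: v for k, v in profile.meta.items() if not isinstance(v, (dict, list, tuple))}
    with atomic_write(path) as fh:
        for k, v in _provenance({**meta, **(header or {})}).items():
            fh.write(f"# {k} = {v}\n")
        sigma = profile.sigma if profile.sigma is not None else np.full_like(profile.z, np.nan)
        extra = getattr(profile, "cumulative", None)
        # resistance profiles carry their running integral as a 4th column
        fh.write("z_nm\tvalue\tsigma" + ("\tcumulative\n" if extra is not None else "\n"))
        for i in range(profile.z.size):
            fh.write(f"{profile.z[i]:.12g}\t{profile.values[i]:.12g}\t{sigma[i]:.12g}")
            if extra is not None:
                fh.write(f"\t{extra[i]:.12g}")
            fh.write("\n")


def read_profile(path) -> Profile:
    """Read a profile TSV back into a :class:`Profile` (kind-aware)."""
    meta = {}
    rows = []
    with open(path) as fh:
        for raw in fh:
            s = raw.strip()
            if not s:
                continue
            if s.startswith("#"):
                if "=" in s:
                    k, v = s.lstrip("# ").split("=", 1)
                    meta[k.strip()] = _parse_scalar(v.strip())
                continue
            if s.startswith("z_nm"):
                continue
            rows.append([float(x) for x in s.split("\t")])
    if len(rows) < 2:
        raise ValidationError(f"{path}: profile needs at least two rows")
    arr = np.asarray(rows, dtype=float)
    z, vals = arr[:, 0], arr[:, 1]
    sigma = arr[:, 2] if arr.shape[1] > 2 and np.isfinite(arr[:, 2]).any() else None
    kind = meta.get("kind", "")
    if kind == "resistance" and arr.shape[1] > 3:
        return ResistanceProfile(z, vals, arr[:, 3], sigma=sigma, meta=meta)
    cls = _PROFILE_CLASSES.get(kind, Profile)
    if cls is ResistanceProfile:
        cls = Profile  # no cumulative column present
    return cls(z, vals, sigma=sigma, meta=meta)


def _parse_scalar(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v


def write_result(path, result, header: dict | None = None) -> None:
    """Serialize a :class:`PermeabilityResult`-like object to JSON."""
    payload = {
        "P_m_per_s": result.p,
        "sigma_P_m_per_s": result.sigma_p,
        "z1_nm": result.z1,
        "z2_nm": result.z2,
        "temperature_K": result.temperature,
        "units": result.units,
        "settings": _jsonable(result.settings),
        "provenance": _provenance(header),
    }
    with atomic_write(path) as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_result(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunables of one pipeline run; serializes round-trip stable."""

    temperature: float = DEFAULT_TEMPERATURE
    bin_width: float = 0.05
    wham_tol: float = 1e-6
    wham_max_iter: int = 100_000
    bulk_fraction: float = 0.9
    acf_threshold: float = 0.01
    tail_correction: bool = True
    attribute: str = "mean"
    n_boot: int = 0
    block_length: int | None = None
    seed: int = 0
    z1: float | None = None
    z2: float | None = None

    def __post_init__(self) -> None:
        for name in ("temperature", "bin_width", "wham_tol", "acf_threshold"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 < self.bulk_fraction < 1):
            raise ValidationError("bulk_fraction must lie in (0, 1)")
        if self.wham_max_iter < 1 or self.n_boot < 0:
            raise ValidationError("wham_max_iter >= 1 and n_boot >= 0 required")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def hash(self) -> str:
        """Short stable digest identifying this configuration."""
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]
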