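"""File formats and run configuration.

Trace files are plain TSV with ``# key=value`` metadata headers (units are
declared and validated, never guessed); SMD pull-force series use the
GROMACS xvg-style two-column text layout ('#'/'@' comment lines ignored);
sequences arrive as FASTA and structures as PDB, both read through
biotite.  Events tables and kinetics reports are emitted as TSV / JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.sequence.io.fasta as fasta_io
import biotite.structure.io.pdb as pdb_io

from .simulate import ForceExtensionTrace, PullingProtocol

__all__ = [
    "write_trace",
    "read_trace",
    "parse_xvg",
    "read_fasta",
    "read_pdb_structure",
    "read_pdb_ca",
    "events_table",
    "write_events_table",
    "RunConfig",
]

_TRACE_MAGIC = "polyforce-trace v1"
_TRACE_UNITS = "extension:nm force:pN"
_FLOAT_FMT = "%.17g"  # lossless round-trip for float64


# --------------------------------------------------------------------------
# Trace TSV dialect
# --------------------------------------------------------------------------

def write_trace(path, trace: ForceExtensionTrace) -> None:
    """Write a force-extension trace in the package's TSV dialect."""
    path = Path(path)
    proto = trace.protocol
    lines = [
        f"# {_TRACE_MAGIC}",
        f"# units={_TRACE_UNITS}",
        f"# speed={_FLOAT_FMT % proto.speed}",
        f"# spring_constant={_FLOAT_FMT % proto.spring_constant}",
        f"# noise_sigma={_FLOAT_FMT % proto.noise_sigma}",
        f"# max_force={_FLOAT_FMT % proto.max_force}",
        f"# seed={proto.seed}",
    ]
    if proto.time_step is not None:
        lines.append(f"# time_step={_FLOAT_FMT % proto.time_step}")
    for key, value in sorted(trace.metadata.items()):
        if isinstance(value, float):
            value = _FLOAT_FMT % value
        lines.append(f"# {key}={value}")
    lines.append("extension_nm\tforce_pN")
    for x, f in zip(trace.extension, trace.force):
        lines.append(f"{_FLOAT_FMT % x}\t{_FLOAT_FMT % f}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path) -> ForceExtensionTrace:
    """Read a trace written by :func:`write_trace` (exact round-trip)."""
    path = Path(path)
    meta: dict[str, str] = {}
    ext: list[float] = []
    frc: list[float] = []
    saw_header = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if not saw_header:
                if line.split("\t") != ["extension_nm", "force_pN"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected column header "
                        f"'extension_nm<TAB>force_pN', got {line!r}"
                    )
                saw_header = True
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                ext.append(float(parts[0]))
                frc.append(float(parts[1]))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from err

    units = meta.pop("units", None)
    if units is not None and units != _TRACE_UNITS:
        raise ValueError(f"{path}: unexpected units declaration {units!r}")

    proto_kwargs: dict = {}
    for key in ("speed", "spring_constant", "noise_sigma", "max_force", "time_step"):
        if key in meta:
            proto_kwargs[key] = float(meta.pop(key))
    if "seed" in meta:
        proto_kwargs["seed"] = int(meta.pop("seed"))
    protocol = PullingProtocol(**proto_kwargs)

    metadata: dict = {}
    for key, value in meta.items():
        try:
            metadata[key] = float(value)
        except ValueError:
            metadata[key] = value
    return ForceExtensionTrace(
        extension=np.asarray(ext), force=np.asarray(frc),
        protocol=protocol, metadata=metadata,
    )


# --------------------------------------------------------------------------
# GROMACS xvg-style pull-force series
# --------------------------------------------------------------------------

def parse_xvg(path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a two-column (time, force) xvg-style text file.

    Lines starting with '#' or '@' (comments, legends) are skipped.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}"
                )
            times.append(float(parts[0]))
            values.append(float(parts[1]))
    if not times:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(times), np.asarray(values)


# --------------------------------------------------------------------------
# Sequences and structures
# --------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {id: sequence} (ids truncated at first whitespace)."""
    ff = fasta_io.FastaFile.read(str(path))
    return {header.split()[0]: str(seq) for header, seq in ff.items()}


def read_pdb_structure(path):
    """First model of a PDB file as a biotite ``AtomArray``."""
    pdb = pdb_io.PDBFile.read(str(path))
    return pdb.get_structure(model=1)


def read_pdb_ca(path, chain: str | None = None) -> np.ndarray:
    """C-alpha coordinates (N x 3, A) of one chain (default: all chains)."""
    structure = read_pdb_structure(path)
    mask = structure.atom_name == "CA"
    if chain is not None:
        mask &= structure.chain_id == chain
    coords = structure.coord[mask]
    if coords.shape[0] == 0:
        raise ValueError(f"{path}: no C-alpha atoms found")
    return coords


# --------------------------------------------------------------------------
# Events table
# --------------------------------------------------------------------------

def events_table(dataset) -> pd.DataFrame:
    """Flatten an analyzed dataset into a tidy per-event table."""
    rows = []
    for i, (trace, events) in enumerate(dataset):
        for e in events:
            rows.append(
                {
                    "trace_id": i,
                    "speed_nm_s": trace.protocol.speed,
                    "peak_force_pN": e.peak_force,
                    "contour_length_nm": e.fitted_contour_length,
                    "delta_lc_nm": e.delta_lc_to_next,
                    "loading_rate_pN_s": e.loading_rate,
                    "label": e.domain_label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "trace_id", "speed_nm_s", "peak_force_pN", "contour_length_nm",
            "delta_lc_nm", "loading_rate_pN_s", "label",
        ],
    )


def write_events_table(path, dataset) -> None:
    events_table(dataset).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration with every default recorded in provenance."""

    construct: str = "specai41"
    speeds: tuple[float, ...] = (1000.0,)
    n_traces: int = 100
    spring_constant: float = 50.0
    noise_sigma: float = 8.0
    time_step: float | None = None
    seed: int = 0
    persistence_length: float = 0.4
    temperature: float = 298.0
    smoothing_window: int = 5
    min_drop: float = 30.0
    min_fingerprint_peaks: int = 3
    fingerprint_delta_lc: float = 18.0
    fingerprint_tolerance: float = 4.0
    final_rupture_min_force: float = 300.0
    reference_force: float = 213.0
    reference_speed: float = 1000.0
    force_bin_pN: float = 30.0
    delta_lc_bin_nm: float = 2.0
    gravy_threshold: float = -0.3
    gravy_strict: bool = False
    plddt_min: float = 90.0
    rmsd_max: float = 2.0
    defaults_used: tuple[str, ...] = ()

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        """Load a JSON config; unspecified fields keep (and record) defaults."""
        data = json.loads(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)} - {"defaults_used"}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "speeds" in data:
            data["speeds"] = tuple(float(s) for s in data["speeds"])
        defaults = tuple(sorted(names - set(data)))
        return cls(**data, defaults_used=defaults)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
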