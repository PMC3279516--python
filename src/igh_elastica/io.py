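"""File round trips and run manifests.

Traces travel as TSV (columns ``time_s``, ``stage_nm``, ``extension_nm``,
``force_pN``, six decimals) with a JSON sidecar holding protocol
metadata and the event log.  Every CLI run writes a manifest recording
the configuration hash, seed, package version and input checksums, so a
run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from igh_elastica.extension import Element, FilamentArchitecture
from igh_elastica.mechanics import ForceExtensionTrace

__all__ = [
    "write_trace",
    "read_trace",
    "run_manifest",
    "validate_manifest",
    "load_architecture",
    "load_domains",
    "write_distance_tsv",
    "MANIFEST_SCHEMA",
]

TRACE_COLUMNS = ("time_s", "stage_nm", "extension_nm", "force_pN")


def write_trace(trace: ForceExtensionTrace, path) -> None:
    """Write a trace as TSV plus a JSON sidecar (same stem, .json).

    Arrays are formatted with six decimals; write-then-read reproduces
    them to that precision and the metadata exactly.  Refuses to write
    an empty trace.
    """
    if len(trace) == 0:
        raise ValueError("refusing to write an empty trace")
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "stage_nm": trace.stage_position,
            "extension_nm": trace.molecular_extension,
            "force_pN": trace.force,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {
        "events": [[float(t), str(lbl), str(kind)] for t, lbl, kind in trace.events],
        "metadata": trace.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=float))


def read_trace(path) -> ForceExtensionTrace:
    """Read a trace TSV (and its JSON sidecar when present)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: trace file contains no samples")
    t = df["time_s"].to_numpy(float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    events: list = []
    metadata: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        events = [(float(t_), str(l), str(k)) for t_, l, k in data.get("events", [])]
        metadata = data.get("metadata", {})
    return ForceExtensionTrace(
        time=t,
        stage_position=df["stage_nm"].to_numpy(float),
        molecular_extension=df["extension_nm"].to_numpy(float),
        force=df["force_pN"].to_numpy(float),
        events=events,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Manifests

MANIFEST_SCHEMA = {
    "required": [
        "subcommand",
        "config",
        "config_sha256",
        "seed",
        "package_version",
        "inputs",
        "results",
    ]
}


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sha256_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=float).encode()
    ).hexdigest()


def run_manifest(
    subcommand: str,
    config: dict,
    seed: int | None,
    input_paths: list = (),
    results: dict | None = None,
) -> dict:
    """Build a reproducibility manifest for one completed run."""
    from igh_elastica import __version__

    inputs = {str(p): _sha256_file(Path(p)) for p in input_paths}
    results = results or {}
    return {
        "subcommand": subcommand,
        "config": config,
        "config_sha256": _sha256_obj(config),
        "seed": seed,
        "package_version": __version__,
        "inputs": inputs,
        "results": results,
        "results_sha256": _sha256_obj(results),
    }


def validate_manifest(manifest: dict) -> None:
    missing = [k for k in MANIFEST_SCHEMA["required"] if k not in manifest]
    if missing:
        raise ValueError(f"manifest missing required keys: {', '.join(missing)}")


# ---------------------------------------------------------------------------
# Configuration files


def load_architecture(path) -> FilamentArchitecture:
    """Load a filament architecture from YAML/JSON.

    Schema::

        symmetry: monomer | dimer
        elements:
          - {kind: ig_domain, residues: 94, folded_axial_extent: 29.0, label: My9}
          - {kind: helix_linker, residues: 15, label: H9-10}

    Unknown keys are rejected.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: architecture file must be a mapping")
    unknown = set(data) - {"symmetry", "elements"}
    if unknown:
        raise ValueError(f"{path}: unknown keys: {', '.join(sorted(unknown))}")
    elems = []
    for i, entry in enumerate(data.get("elements", [])):
        extra = set(entry) - {"kind", "residues", "folded_axial_extent", "label"}
        if extra:
            raise ValueError(
                f"{path}: element {i}: unknown keys: {', '.join(sorted(extra))}"
            )
        elems.append(
            Element(
                kind=entry["kind"],
                residue_count=int(entry["residues"]),
                folded_axial_extent=float(entry.get("folded_axial_extent", 0.0)),
                label=str(entry.get("label", "")),
            )
        )
    return FilamentArchitecture(elems, symmetry=data.get("symmetry", "monomer"))


def load_domains(path) -> list:
    """Load domain boundaries from YAML: list of {label, chain, first, last}."""
    from igh_elastica.geometry import Domain

    data = yaml.safe_load(Path(path).read_text())
    domains = []
    for i, entry in enumerate(data):
        extra = set(entry) - {"label", "chain", "first", "last"}
        if extra:
            raise ValueError(
                f"{path}: domain {i}: unknown keys: {', '.join(sorted(extra))}"
            )
        domains.append(
            Domain(
                label=str(entry["label"]),
                chain_id=str(entry["chain"]),
                first_residue=int(entry["first"]),
                last_residue=int(entry["last"]),
            )
        )
    return domains


def write_distance_tsv(dist, path) -> None:
    """Write a distance histogram as TSV with columns r_lo, r_hi, count."""
    df = pd.DataFrame(
        {
            "r_lo": dist.bin_edges[:-1],
            "r_hi": dist.bin_edges[1:],
            "count": dist.counts,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
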