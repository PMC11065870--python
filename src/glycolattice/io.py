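"""Readers, writers, pipeline configuration and the orchestrating pipeline.

Spectra travel as two-column (m/z, intensity) text — whitespace- or
comma-delimited, ``#`` comments — or optionally mzML; mass distributions and
annotation tables as CSV with units in the header; mass-photometry events as
a one-column CSV in kDa.  All writes are atomic (temp file + rename), and
every numeric artifact records the seed and config hash that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .glycomass import AdductTable, PROTON_MASS
from .synthesize import (
    MPHistogram,
    SimulationConfig,
    Spectrum,
    fit_mp_mixture,
    population_distribution,
    render_spectrum,
    sample_proteoforms,
)
from .deconvolve import MassDistribution, centroid, infer_charges, zero_charge
from .annotate import assign_lattice
from .oligomer import convolve_assembly, compare_assembly

__all__ = [
    "ParseError",
    "PipelineConfig",
    "atomic_write",
    "read_spectrum",
    "write_spectrum",
    "read_mass_distribution",
    "write_mass_distribution",
    "read_mp_events",
    "write_mp_events",
    "run_pipeline",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending path and line."""

    def __init__(self, path, line_no: int | None, message: str):
        self.path = str(path)
        self.line_no = line_no
        where = f"{path}" + (f":{line_no}" if line_no is not None else "")
        super().__init__(f"{where}: {message}")


@contextmanager
def atomic_write(path, mode: str = "w") -> Iterator:
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_spectrum(path, format: str = "text") -> Spectrum:
    """Read a spectrum from two-column text or an mzML file.

    Text: whitespace- or comma-delimited m/z and intensity columns; ``#``
    starts a comment.  An unsorted axis is auto-sorted with a warning flag in
    the metadata; duplicate or malformed lines raise :class:`ParseError` with
    the line number.
    """
    path = Path(path)
    if format == "mzml":
        return _read_mzml(path)
    if format != "text":
        raise ValueError(f"unknown spectrum format {format!r}")
    mz: List[float] = []
    intensity: List[float] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ParseError(path, line_no, f"expected two columns, got {raw!r}")
            try:
                mz.append(float(parts[0]))
                intensity.append(float(parts[1]))
            except ValueError:
                raise ParseError(path, line_no, f"non-numeric value in {raw!r}") from None
    if not mz:
        raise ParseError(path, None, "no data rows")
    mz_arr = np.asarray(mz)
    int_arr = np.asarray(intensity)
    metadata: Dict[str, object] = {"kind": "measured", "source": str(path)}
    if np.any(np.diff(mz_arr) <= 0):
        order = np.argsort(mz_arr, kind="stable")
        mz_arr, int_arr = mz_arr[order], int_arr[order]
        keep = np.concatenate([[True], np.diff(mz_arr) > 0])
        mz_arr, int_arr = mz_arr[keep], int_arr[keep]
        metadata["sorted_on_read"] = True
    return Spectrum(mz_arr, int_arr, metadata)


def _read_mzml(path) -> Spectrum:
    # prefer pyteomics when its full PSI stack is importable; otherwise fall
    # back to a minimal reader for plain MS1 scans (64/32-bit float arrays,
    # zlib or no compression), which covers the profile exports this
    # package consumes
    try:
        from pyteomics import mzml

        with mzml.read(str(path)) as reader:
            for scan in reader:
                if scan.get("ms level", 1) == 1:
                    return Spectrum(
                        np.asarray(scan["m/z array"], dtype=float),
                        np.asarray(scan["intensity array"], dtype=float),
                        {"kind": "measured", "source": str(path), "id": scan.get("id")},
                    )
        raise ParseError(path, None, "no MS1 scan found")
    except ParseError:
        raise
    except Exception:
        return _read_mzml_minimal(path)


def _read_mzml_minimal(path) -> Spectrum:
    """Dependency-light mzML MS1 reader: base64 binary arrays via stdlib."""
    import base64
    import struct
    import xml.etree.ElementTree as ET
    import zlib

    ns = {"mz": "http://psi.hupo.org/ms/mzml"}

    def local(tag):
        return tag.rsplit("}", 1)[-1]

    tree = ET.parse(path)
    root = tree.getroot()
    for spectrum in root.iter():
        if local(spectrum.tag) != "spectrum":
            continue
        params = {
            p.get("accession"): p.get("value")
            for p in spectrum.iter()
            if local(p.tag) == "cvParam"
        }
        if params.get("MS:1000511", "1") != "1":  # ms level
            continue
        arrays: Dict[str, np.ndarray] = {}
        for bda in spectrum.iter():
            if local(bda.tag) != "binaryDataArray":
                continue
            accs = {
                p.get("accession")
                for p in bda.iter()
                if local(p.tag) == "cvParam"
            }
            binary = next(
                (e for e in bda.iter() if local(e.tag) == "binary"), None
            )
            if binary is None or binary.text is None:
                continue
            raw = base64.b64decode(binary.text)
            if "MS:1000574" in accs:  # zlib compression
                raw = zlib.decompress(raw)
            fmt = "d" if "MS:1000523" in accs else "f"  # 64- vs 32-bit float
            values = np.array(struct.unpack(f"<{len(raw) // (8 if fmt == 'd' else 4)}{fmt}", raw))
            if "MS:1000514" in accs:
                arrays["mz"] = values
            elif "MS:1000515" in accs:
                arrays["intensity"] = values
        if "mz" in arrays and "intensity" in arrays:
            return Spectrum(
                arrays["mz"],
                arrays["intensity"],
                {"kind": "measured", "source": str(path), "id": spectrum.get("id")},
            )
    raise ParseError(path, None, "no MS1 scan found")


def write_spectrum(spec: Spectrum, path) -> None:
    with atomic_write(path) as fh:
        fh.write("# mz_per_charge\tintensity_arb\n")
        for m, i in zip(spec.mz, spec.intensity):
            fh.write(f"{m:.6f}\t{i:.8g}\n")


def write_mass_distribution(md: MassDistribution, path, metadata: Dict | None = None) -> None:
    frame = pd.DataFrame({"mass_Da": md.masses, "abundance_arb": md.abundance})
    with atomic_write(path) as fh:
        if metadata:
            fh.write(f"# {json.dumps(metadata, sort_keys=True)}\n")
        frame.to_csv(fh, index=False)


def read_mass_distribution(path) -> MassDistribution:
    frame = pd.read_csv(path, comment="#")
    if "mass_Da" not in frame or "abundance_arb" not in frame:
        raise ParseError(path, None, "expected columns mass_Da, abundance_arb")
    return MassDistribution(frame["mass_Da"].to_numpy(), frame["abundance_arb"].to_numpy())


def write_mp_events(hist: MPHistogram, path) -> None:
    with atomic_write(path) as fh:
        fh.write("mass_kDa\n")
        for e in hist.events:
            fh.write(f"{e:.4f}\n")


def read_mp_events(path) -> MPHistogram:
    frame = pd.read_csv(path, comment="#")
    col = "mass_kDa" if "mass_kDa" in frame else frame.columns[0]
    return MPHistogram(events=frame[col].to_numpy(dtype=float))


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; serializes losslessly to/from YAML."""

    out_dir: str = "glycolattice_out"
    seed: int = 0
    simulate: bool = True
    spectrum_path: str | None = None  # used when simulate is False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    z_range: Tuple[int, int] = (15, 35)
    repeat_filter: float | None = 72.95
    grid_step: float = 0.5
    base_mass: float | None = None  # lattice anchor; inferred when None
    lattice_spacing: float = 365.33
    residue_ranges: Dict[str, int] = field(
        default_factory=lambda: {"branch": 24, "Fuc": 8, "Neu5Ac": 16}
    )
    tol: float = 2.0
    min_snr: float = 3.0
    smooth_fwhm: float | None = None
    oligomer_order: int = 2
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["simulation"] = dataclasses.asdict(self.simulation)
        payload["simulation"]["core_glycans"] = dict(self.simulation.core_glycans)
        with atomic_write(path) as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: Dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        payload = dict(payload)
        if "simulation" in payload and isinstance(payload["simulation"], dict):
            sim = dict(payload["simulation"])
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulation keys: {sorted(sim_unknown)}")
            if "core_glycans" in sim and isinstance(sim["core_glycans"], dict):
                from .glycomass import GlycanComposition

                sim["core_glycans"] = GlycanComposition(sim["core_glycans"])
            for key in ("branch_weights", "antennary_fuc_weights", "neu5ac_weights"):
                if key in sim:
                    sim[key] = {int(k): float(v) for k, v in sim[key].items()}
            if "lipid_site_probs" in sim:
                sim["lipid_site_probs"] = {
                    k: (int(v[0]), float(v[1]))
                    for k, v in sim["lipid_site_probs"].items()
                }
            payload["simulation"] = SimulationConfig(**sim)
        if "z_range" in payload:
            payload["z_range"] = tuple(int(z) for z in payload["z_range"])
        return cls(**payload)

    def config_hash(self) -> str:
        # fingerprint of the scientific parameters only: where outputs go and
        # how chatty the log is must not change what the numbers are
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Simulate (optionally), deconvolve, annotate and model assembly.

    Writes every artifact under ``cfg.out_dir`` tagged with the config hash
    and seed; returns a report dict of the key results.  A stage failure
    leaves earlier artifacts on disk and is re-raised after logging.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    report: Dict[str, object] = dict(meta)

    if cfg.simulate:
        sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        population = sample_proteoforms(sim)
        spectrum = render_spectrum(population, sim)
        write_spectrum(spectrum, out / "spectrum.txt")
        truth = pd.DataFrame(
            {
                "label": [p.label for p in population],
                "mass_Da": [p.mass() for p in population],
                "abundance": [p.abundance for p in population],
            }
        )
        with atomic_write(out / "truth.csv") as fh:
            truth.to_csv(fh, index=False)
        report["n_proteoforms"] = len(population)
        base_mass = cfg.base_mass if cfg.base_mass is not None else sim.lattice_base_mass
    else:
        if not cfg.spectrum_path or not Path(cfg.spectrum_path).exists():
            raise FileNotFoundError(f"spectrum not found: {cfg.spectrum_path}")
        spectrum = read_spectrum(cfg.spectrum_path)
        base_mass = cfg.base_mass

    peaks = centroid(spectrum, min_snr=cfg.min_snr, smooth_fwhm=cfg.smooth_fwhm)
    assignment = infer_charges(peaks, z_range=cfg.z_range)
    if not assignment.series:
        raise RuntimeError("charge inference found no consistent series")
    main_species = max(
        assignment.species_masses, key=lambda s: sum(
            float(cs.member_intensity.sum()) for cs in assignment.by_species(s)
        )
    )
    md = zero_charge(
        assignment.by_species(main_species),
        repeat_filter=cfg.repeat_filter,
        grid_step=cfg.grid_step,
    )
    write_mass_distribution(md, out / "massdist.csv", metadata=meta)
    report["species_masses"] = dict(assignment.species_masses)

    if base_mass is None:
        from .annotate import infer_base_mass

        base_mass, _ = infer_base_mass(md, cfg.lattice_spacing)
    result = assign_lattice(
        md, base_mass, cfg.residue_ranges, AdductTable.default(), tol=cfg.tol
    )
    rows = []
    labels = result.relabelled()
    for pa, lab in zip(result.peaks, labels):
        rows.append(
            {
                "mass_Da": pa.mass,
                "abundance_arb": pa.abundance,
                "label": lab,
                "n_candidates": len(pa.candidates),
                "error_Da": pa.primary.error if pa.primary else np.nan,
            }
        )
    with atomic_write(out / "annotation.csv") as fh:
        pd.DataFrame(rows).to_csv(fh, index=False)
    report["n_assigned"] = len(result.assigned)
    report["n_unassigned"] = len(result.unassigned)

    norm = md.normalize()
    predicted = convolve_assembly(norm, cfg.oligomer_order)
    report["subunit_mean_Da"] = norm.mean()
    report["oligomer_mean_Da"] = predicted.mean()
    write_mass_distribution(predicted, out / "oligomer_predicted.csv", metadata=meta)

    with atomic_write(out / "report.json") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
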