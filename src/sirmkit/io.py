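"""Format readers/writers, configuration, and pipeline plumbing.

All delimited text is tab-separated UTF-8 with '.' decimals; missing values
are empty fields.  Writers and their paired readers round-trip losslessly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import derive_seed
from .mid import MIDVector

SEP = "\t"


class ParseError(ValueError):
    pass


def read_expression_matrix(path, sep: str = SEP) -> pd.DataFrame:
    """Gene x sample matrix from delimited text (first column = gene ids).

    Duplicate gene rows (multiple probes per gene) are summarized by the
    median log2 expression; duplicate sample names or non-numeric cells are
    parse errors.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ParseError(f"{path}: empty or missing expression matrix")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen, dupes = set(), set()
    for name in header:
        (dupes if name in seen else seen).add(name)
    if dupes:
        raise ParseError(f"{path}: duplicate sample names {sorted(dupes)}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise ParseError(f"{path}: no data rows/columns")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row_pos = int(np.argwhere(bad.to_numpy())[0][0])
        col = bad.columns[int(np.argwhere(bad.to_numpy())[0][1])]
        raise ParseError(
            f"{path}: non-numeric cell at line {row_pos + 2}, column {col!r}: "
            f"{df.iloc[row_pos][col]!r}"
        )
    numeric.index.name = "gene"
    if numeric.index.duplicated().any():
        numeric = numeric.groupby(level=0).median()
    return numeric


def write_expression_matrix(matrix: pd.DataFrame, path, sep: str = SEP) -> None:
    matrix.to_csv(path, sep=sep, index_label="gene")


def read_geo_series_matrix(path) -> pd.DataFrame:
    """GEO series-matrix-style expression text: header block ('!' lines) skipped."""
    path = Path(path)
    lines = path.read_text().splitlines()
    start = next((i for i, ln in enumerate(lines) if not ln.startswith(("!", "#"))), None)
    if start is None:
        raise ParseError(f"{path}: no table found after header block")
    end = next((i for i in range(start, len(lines)) if lines[i].startswith("!")), len(lines))
    from io import StringIO

    body = "\n".join(lines[start:end])
    df = pd.read_csv(StringIO(body), sep=SEP, index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce").dropna(how="all")
    if df.index.duplicated().any():
        df = df.groupby(level=0).median()
    return df


def read_isotopologue_table(path, sep: str = SEP) -> pd.DataFrame:
    from .sirm import validate_table

    table = pd.read_csv(path, sep=sep)
    table["fragment_mz"] = table["fragment_mz"].astype(int)
    table["mass_shift"] = table["mass_shift"].astype(int)
    validate_table(table)
    return table


def write_isotopologue_table(table: pd.DataFrame, path, sep: str = SEP) -> None:
    table.to_csv(path, sep=sep, index=False)


def read_reference_spectrum(path, metabolite: str, fragment_mz: int, sep: str = SEP):
    """Two-column (shift, fraction) file -> ReferenceSpectrum."""
    from .sirm import ReferenceSpectrum

    df = pd.read_csv(path, sep=sep)
    shifts = df.iloc[:, 0].astype(int).to_numpy()
    fracs = df.iloc[:, 1].astype(float).to_numpy()
    masses = np.zeros(shifts.max() + 1)
    masses[shifts] = fracs
    return ReferenceSpectrum(metabolite, fragment_mz, MIDVector.from_intensities(masses))


def write_reference_spectrum(ref, path, sep: str = SEP) -> None:
    pd.DataFrame(
        {"mass_shift": np.arange(len(ref.mid)), "fraction": ref.mid.masses}
    ).to_csv(path, sep=sep, index=False)


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class PipelineConfig:
    """Validated stage parameters plus the global seed.

    Round-trips losslessly through YAML.
    """

    seed: int = 0
    q: float = 0.10
    n_draws: int = 1000
    p13c: float = 0.0107
    or_bounds: tuple[float, float] = (0.1, 2.0)
    linkage: str = "average"
    multiplicative_cv: float = 0.0
    additive_floor: float = 0.0
    n_bootstrap: int = 200
    log_level: str = "INFO"
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q={self.q} outside (0, 1)")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not 0.0 <= self.p13c <= 0.05:
            raise ValueError(f"p13c={self.p13c} outside [0, 0.05]")
        low, high = self.or_bounds
        if not 0.0 <= low < high:
            raise ValueError(f"or_bounds {self.or_bounds} must satisfy 0 <= low < high")
        self.or_bounds = (float(low), float(high))
        if self.linkage not in ("average", "single", "complete", "ward"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.multiplicative_cv < 0 or self.additive_floor < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "or_bounds" in raw:
            raw["or_bounds"] = tuple(raw["or_bounds"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["or_bounds"] = list(self.or_bounds)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def stage_seed(self, tag: str) -> int:
        return derive_seed(self.seed, tag)


@dataclass
class RunManifest:
    """Provenance record emitted once per pipeline run."""

    config: dict
    input_checksums: dict
    package_version: str = __version__
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def record_stage(self, name: str, seconds: float, **info) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 4), **info})

    def write(self, path) -> None:
        payload = {
            "package_version": self.package_version,
            "config": self.config,
            "input_checksums": self.input_checksums,
            "stages": self.stages,
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Demo pipeline: simulate citrate tracer tables -> quantify -> fit routing.

    Runs the three-tracer citrate experiment with a mid-range routing
    mixture, recovers labelled quantities and corrected MIDs, and fits
    routing fractions.  Deterministic for a fixed config seed; the manifest
    is written to ``out_dir`` regardless of stage failures.
    """
    from . import routing, sirm, synthetic

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums = {str(p): sha256_of(p) for p in config.inputs.values() if Path(str(p)).exists()}
    manifest = RunManifest(config=asdict(config), input_checksums=checksums)
    manifest.config["or_bounds"] = list(config.or_bounds)

    try:
        t0 = time.perf_counter()
        truth = synthetic.RoutingFractions(
            f_ox_glc=0.35, f_ox_gln=0.25, f_red_gln=0.20, f_pc=0.05, f_unlab=0.15, f_fix=0.08
        )
        tables: dict[str, pd.DataFrame] = {}
        corrected: dict[tuple, MIDVector] = {}
        for tracer in (
            synthetic.Tracer.U13C6_GLUCOSE,
            synthetic.Tracer.U13C5_GLUTAMINE,
            synthetic.Tracer.C13_BICARBONATE,
        ):
            mids = synthetic.simulate_citrate_mids(truth, tracer)
            noise = synthetic.NoiseModel(
                config.multiplicative_cv, config.additive_floor,
                seed=config.stage_seed(f"simulate:{tracer.value}"),
            )
            table = synthetic.generate_intensity_table(
                mids, {"citrate": 5e5}, p13c=config.p13c, noise=noise,
                sample_names=("rep1", "rep2", "rep3"),
            )
            tables[tracer.value] = table
            write_isotopologue_table(table, out_dir / f"isotopologues_{tracer.value}.tsv")
            refs = {
                ("citrate", mz): sirm.binomial_reference(frag, config.p13c)
                for mz, frag in synthetic.CITRATE_FRAGMENTS.items()
            }
            for mz, frag in synthetic.CITRATE_FRAGMENTS.items():
                mid = sirm.raw_mid(table, "citrate", mz, "rep1")
                corrected[(tracer.value, mz)] = sirm.natural_abundance_correct(
                    mid, frag, config.p13c
                )
            quantities = sirm.labelled_quantities(table, refs)
            quantities.to_csv(out_dir / f"labelled_quantities_{tracer.value}.tsv", sep=SEP, index=False)
        manifest.record_stage("simulate+sirm", time.perf_counter() - t0, tracers=list(tables))

        t0 = time.perf_counter()
        fit = routing.fit_routing_fractions(
            corrected, n_bootstrap=config.n_bootstrap, seed=config.stage_seed("routing-bootstrap")
        )
        report = {
            "fractions": {k: getattr(fit.fractions, k) for k in routing.PARAM_NAMES},
            "truth": {k: getattr(truth, k) for k in routing.PARAM_NAMES},
            "residual_norm": fit.residual_norm,
            "intervals": fit.intervals,
        }
        (out_dir / "routing_fit.json").write_text(json.dumps(report, indent=2))
        manifest.record_stage("routing-fit", time.perf_counter() - t0, residual=fit.residual_norm)
    finally:
        manifest.write(out_dir / "manifest.json")
    return manifest
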