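"""End-to-end analysis pipeline and report rendering.

Wires the readers → shell structure → shell dynamics stages from a single
declarative YAML configuration and writes, in order, ``rdf.tsv``,
``shell.json``, ``dynamics.json`` and a ``manifest.json`` recording the
config hash, seed and package version.  All floating-point output keeps full
precision in the machine-readable files; rounding to the printed precision
(2 decimals for Å, 1 for CN, whole ps for residence times) happens only in
the rendered comparison tables.  Timestamps appear only in the manifest so
repeated runs with identical inputs are byte-identical elsewhere.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .shell_dynamics import (
    CNLifetimeSpectrum,
    MRTResult,
    cn_lifetimes,
    compare_ions,
    detect_exchanges,
    mrt_direct,
    round_half_up,
)
from .shell_structure import (
    ShellDefinition,
    compute_rdf,
    compute_shell_metrics,
    cn_histogram,
    find_first_minimum,
    shell_occupancy,
)
from .trajectory_io import assign_water_topology, read_xdatcar, read_xyz

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "render_comparison"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_KNOWN_KEYS = {
    "input_path",
    "input_format",
    "dt_fs",
    "solute_species",
    "bond_cutoff_angstrom",
    "rdf_bin_width",
    "rdf_r_max",
    "shell_method",
    "shell_r_boundary",
    "shell_smoothing_window",
    "t_star_ps",
    "output_dir",
    "seed",
    "log_level",
}


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one analysis run."""

    input_path: str
    dt_fs: float
    solute_species: str
    output_dir: str
    input_format: str = "xyz"  # "xyz" | "xdatcar"
    bond_cutoff_angstrom: float = 1.25
    rdf_bin_width: float = 0.02
    rdf_r_max: float | None = None
    shell_method: str = "first-minimum"  # or "fixed"
    shell_r_boundary: float | None = None
    shell_smoothing_window: int = 5
    t_star_ps: tuple[float, ...] = (0.0, 0.5)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_format not in ("xyz", "xdatcar"):
            raise ConfigError(f"unknown input_format {self.input_format!r}")
        if self.shell_method not in ("first-minimum", "fixed"):
            raise ConfigError(f"unknown shell_method {self.shell_method!r}")
        if self.shell_method == "fixed" and self.shell_r_boundary is None:
            raise ConfigError("shell_method 'fixed' requires shell_r_boundary")
        object.__setattr__(self, "t_star_ps", tuple(float(t) for t in self.t_star_ps))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "input_format": self.input_format,
            "dt_fs": self.dt_fs,
            "solute_species": self.solute_species,
            "bond_cutoff_angstrom": self.bond_cutoff_angstrom,
            "rdf_bin_width": self.rdf_bin_width,
            "rdf_r_max": self.rdf_r_max,
            "shell_method": self.shell_method,
            "shell_r_boundary": self.shell_r_boundary,
            "shell_smoothing_window": self.shell_smoothing_window,
            "t_star_ps": list(self.t_star_ps),
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run readers → structure → dynamics and write the report bundle.

    Returns the in-memory bundle (the same content as the written files).
    On a stage failure the exception propagates after the manifest records
    the failing stage; earlier outputs are retained.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "started_unix": time.time(),
        "stages": [],
    }

    def fail(stage: str, exc: Exception) -> None:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    # --- read -----------------------------------------------------------
    try:
        reader = read_xyz if config.input_format == "xyz" else read_xdatcar
        traj = reader(config.input_path, config.dt_fs, config.solute_species)
        topo = assign_water_topology(traj, config.bond_cutoff_angstrom)
        manifest["stages"].append("read")
    except Exception as exc:
        fail("read", exc)
        raise

    # --- structure --------------------------------------------------------
    try:
        rdf = compute_rdf(
            traj, "O", bin_width=config.rdf_bin_width, r_max=config.rdf_r_max
        )
        (outdir / "rdf.tsv").write_text(rdf.to_tsv())
        if config.shell_method == "fixed":
            shell_def = ShellDefinition(float(config.shell_r_boundary), "fixed")
        else:
            shell_def = find_first_minimum(rdf, config.shell_smoothing_window)
        series = shell_occupancy(traj, topo, shell_def)
        metrics = compute_shell_metrics(traj, topo, series)
        hist = cn_histogram(series)
        shell_payload = {
            "boundary_angstrom": shell_def.r_boundary,
            "boundary_method": shell_def.method,
            "cn_histogram": {str(k): v for k, v in sorted(hist.items())},
            "metrics": json.loads(metrics.to_json()),
        }
        (outdir / "shell.json").write_text(
            json.dumps(shell_payload, indent=2, sort_keys=True)
        )
        manifest["stages"].append("structure")
    except Exception as exc:
        fail("structure", exc)
        raise

    # --- dynamics ---------------------------------------------------------
    try:
        dyn: dict[str, dict] = {}
        for t_star in config.t_star_ps:
            log = detect_exchanges(series, t_star)
            mrt = mrt_direct(series, t_star)
            spectrum = cn_lifetimes(series, t_star)
            dyn[f"{t_star:g}"] = {
                "t_star_ps": t_star,
                "n_ex": log.n_ex,
                "t_samp_ps": mrt.t_samp,
                "cn_av": mrt.cn_av,
                "mrt_ps": mrt.mrt,
                "lifetimes": {
                    str(cn): {"mean_ps": v[0], "longest_ps": v[1], "episodes": v[2]}
                    for cn, v in sorted(spectrum.lifetimes.items())
                },
            }
        (outdir / "dynamics.json").write_text(json.dumps(dyn, indent=2, sort_keys=True))
        manifest["stages"].append("dynamics")
    except Exception as exc:
        fail("dynamics", exc)
        raise

    manifest["finished_unix"] = time.time()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "shell": shell_payload,
        "dynamics": dyn,
        "metrics": metrics,
        "series": series,
        "rdf": rdf,
    }


# ---------------------------------------------------------------------------
# comparison rendering
# ---------------------------------------------------------------------------

_FORMATS = {
    "r_bar_angstrom": "{:.2f}",
    "cn_mean": "{:.1f}",
    "tilt_mean_deg": "{:.0f}",
    "sigma2_angstrom2": "{:.3f}",
    "eccentricity_angstrom": "{:.2f}",
}


def _fmt(name: str, value) -> str:
    if value is None:
        return "–"
    if name.startswith(("mrt_ps", "longest_cn_lifetime")):
        return str(round_half_up(value))
    if name.startswith("n_ex"):
        return str(int(value))
    return _FORMATS.get(name, "{:.4g}").format(value)


def render_comparison(
    rows: list[dict[str, object]], label_a: str = "A", label_b: str = "B"
) -> tuple[str, str]:
    """Render :func:`compare_ions` rows as aligned text and as TSV.

    Numeric formatting matches the conventions of the printed tables
    (2 decimals for Å, 1 for CN, integers for ps residence times); missing
    values render as "–".
    """
    header = ["property", label_a, label_b, "flag"]
    table = [header]
    tsv_lines = ["\t".join(header)]
    for row in rows:
        name = str(row["property"])
        cells = [
            name,
            _fmt(name, row[label_a]),
            _fmt(name, row[label_b]),
            str(row["flag"]),
        ]
        table.append(cells)
        tsv_lines.append("\t".join(cells))
    widths = [max(len(r[c]) for r in table) for c in range(4)]
    text_lines = [
        "  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in table
    ]
    return "\n".join(text_lines) + "\n", "\n".join(tsv_lines) + "\n"
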