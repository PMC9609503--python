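"""End-to-end pipeline orchestration plus protocol arithmetic utilities.

``run_pipeline`` drives preprocess -> Amide I deconvolution -> marker series
-> sigmoid kinetics -> lag-phase classification from a single config mapping
(plus an optional structure stage), writing CSV/JSON outputs whose headers
carry the config hash for provenance.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .exceptions import ConfigError, DomainError
from .kinetics import DEFAULT_LAG_THRESHOLD_H, classify_kinetics, fit_sigmoid
from .markers import build_marker_series
from .peakfit import deconvolve_amide1
from .preprocess import DEFAULT_ANCHORS, preprocess
from .spectra_io import read_spectrum, write_spectrum
from .structure import com_distance_series, detect_interactions, write_structure
from .synthetic import (
    ContactSpec,
    KineticParams,
    generate_dimer_trajectory,
    generate_timecourse,
    ground_truth_json,
)

EXTINCTION_COEFF_LYSOZYME = 37970.0  # M^-1 cm^-1 at 280 nm


def protein_concentration(absorbance_280: float) -> float:
    """Lysozyme concentration in uM from A280: A * 1e7 / 37970."""
    if absorbance_280 < 0:
        raise DomainError("absorbance must be non-negative")
    return absorbance_280 * 1e7 / EXTINCTION_COEFF_LYSOZYME


def titration_concentration(
    additions: list[tuple[float, float]],
    sample_volume_ml: float,
    include_added_volume: bool = False,
) -> float:
    """Final concentration (mM) after adding stock aliquots to a sample.

    ``additions`` are (volume in uL, stock molarity in M) pairs.  By default
    the added aliquot volume is not counted in the denominator, matching the
    usual bench arithmetic for uL-scale additions to mL-scale samples.
    """
    if sample_volume_ml <= 0:
        raise DomainError("sample volume must be positive")
    if any(v <= 0 for v, _ in additions):
        raise DomainError("aliquot volumes must be positive")
    moles = sum(vol_ul * 1e-6 * stock for vol_ul, stock in additions)
    volume_l = sample_volume_ml * 1e-3
    if include_added_volume:
        volume_l += sum(vol_ul * 1e-6 for vol_ul, _ in additions)
    return moles / volume_l * 1e3


# ---------------------------------------------------------------------------
# Run configuration


_KNOWN_TOP_KEYS = {
    "seed", "outdir", "synthetic", "inputs", "preprocess", "amide1",
    "markers", "kinetics", "structure",
}


def validate_config(config: dict) -> dict:
    """Check the run config before any computation; returns it unchanged."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - _KNOWN_TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise ConfigError("config requires a 'seed'")
    if not isinstance(config["seed"], int):
        raise ConfigError("'seed' must be an integer")
    has_syn = "synthetic" in config
    has_inp = "inputs" in config
    if has_syn == has_inp:
        raise ConfigError("config requires exactly one of 'synthetic' or 'inputs'")
    if has_syn:
        syn = config["synthetic"]
        if not isinstance(syn, dict) or "regime" not in syn:
            raise ConfigError("'synthetic' block requires a 'regime'")
        if syn["regime"] not in ("static", "isodesmic", "nucleated"):
            raise ConfigError(f"unknown regime {syn['regime']!r}")
    if has_inp:
        inp = config["inputs"]
        if not isinstance(inp, dict) or not inp.get("spectra"):
            raise ConfigError("'inputs' block requires a non-empty 'spectra' list")
    return config


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything run_pipeline computed, plus provenance."""

    config_hash: str
    seed: int
    classification: str
    ss_table: list[dict] = field(default_factory=list)  # per time point
    marker_table: list[dict] = field(default_factory=list)
    kinetics_table: list[dict] = field(default_factory=list)
    structure_summary: dict = field(default_factory=dict)
    outdir: str | None = None

    def to_dict(self) -> dict:
        return {
            "provenance": {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": __version__,
            },
            "classification": self.classification,
            "secondary_structure": self.ss_table,
            "markers": self.marker_table,
            "kinetics": self.kinetics_table,
            "structure": self.structure_summary,
        }


def _write_csv(path: Path, header_hash: str, columns: list[str], rows: list[dict]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={header_hash} ramagg={__version__}\n")
        fh.write(",".join(columns) + "\n")
        for row in rows:
            fh.write(",".join(_fmt(row[c]) for c in columns) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.9g}"
    return str(v)


def _load_spectra(config: dict):
    """Returns (spectra, ground_truth_slices | None)."""
    if "synthetic" in config:
        syn = config["synthetic"]
        kp = KineticParams(**syn["kinetics"]) if "kinetics" in syn else None
        kwargs = dict(
            kinetic_params=kp,
            noise_sd=float(syn.get("noise_sd", 0.0)),
            spike_count=int(syn.get("spike_count", 0)),
            seed=int(config["seed"]),
        )
        if syn.get("timepoints"):
            kwargs["timepoints"] = tuple(float(t) for t in syn["timepoints"])
        pairs = generate_timecourse(syn["regime"], **kwargs)
        return [s for s, _ in pairs], [g for _, g in pairs]
    spectra = []
    for p in config["inputs"]["spectra"]:
        with open(p) as fh:
            spectra.append(read_spectrum(fh))
    spectra.sort(key=lambda s: (s.meta.time_h if s.meta.time_h is not None else 0.0))
    return spectra, None


def _structure_stage(config: dict, seed: int) -> tuple[dict, object | None]:
    blk = config.get("structure")
    if not blk:
        return {}, None
    syn = blk.get("synthetic", {})
    contacts = [ContactSpec(**c) for c in syn.get("planted_contacts", [])]
    traj = generate_dimer_trajectory(
        n_frames=int(syn.get("n_frames", 25)),
        com_start=float(syn.get("com_start", 27.19)),
        com_end=float(syn.get("com_end", 23.0)),
        planted_contacts=contacts,
        jitter=float(syn.get("jitter", 0.0)),
        seed=seed,
    )
    coms = com_distance_series(traj, "A", "B")
    _, counts = detect_interactions(traj.frame(traj.n_frames - 1))
    summary = {
        "n_frames": traj.n_frames,
        "com_first_A": float(coms[0]),
        "com_last_A": float(coms[-1]),
        "final_interactions": counts,
    }
    return summary, traj


def run_pipeline(config: dict, outdir: str | Path | None = None) -> RunReport:
    """Execute the full pipeline from a validated config; returns the report.

    With ``outdir`` set (or ``config['outdir']``), writes spectra tables,
    marker/kinetics CSVs, the JSON report and a plain-text summary, every
    file header carrying the config hash.  Identical config + seed produce
    byte-identical outputs.
    """
    validate_config(config)
    chash = config_hash(config)
    seed = int(config["seed"])

    spectra, truths = _load_spectra(config)
    pp = config.get("preprocess", {})
    processed = [
        preprocess(
            s,
            spike_z=float(pp.get("spike_z", 8.0)),
            baseline_method=pp.get("baseline", {}).get("method", "anchor_points"),
            anchors=tuple(pp.get("baseline", {}).get("anchors", DEFAULT_ANCHORS)),
            norm_reference=float(pp.get("norm", {}).get("reference", 1004.0)),
            norm_window=float(pp.get("norm", {}).get("window", 8.0)),
        )
        for s in spectra
    ]

    ss_rows = []
    for s in processed:
        _, ss = deconvolve_amide1(s)
        ss_rows.append(
            {
                "time_h": s.meta.time_h if s.meta.time_h is not None else float("nan"),
                "alpha": ss.alpha,
                "beta_sheet": ss.beta_sheet,
                "beta_turn": ss.beta_turn,
                "coil": ss.coil,
            }
        )

    series = build_marker_series(processed)
    marker_rows = [
        {"marker": ms.name, "time_h": t, "value": v, "sigma": u}
        for ms in series
        for t, v, u in zip(ms.times, ms.values, ms.uncertainties)
    ]

    kin_cfg = config.get("kinetics", {})
    lag_threshold = float(kin_cfg.get("lag_threshold", DEFAULT_LAG_THRESHOLD_H))
    fits = []
    kin_rows = []
    for ms in series:
        if not ms.usable or ms.name == "I1004":
            continue
        try:
            f = fit_sigmoid(ms)
        except Exception:
            continue
        fits.append(f)
        kin_rows.append(
            {
                "marker": ms.name,
                "y0": f.y0, "ymax": f.ymax, "k": f.k, "t50": f.t50,
                "lag": f.lag if f.converged else float("nan"),
                "r2": f.r_squared,
                "converged": f.converged,
                "direction": f.direction,
            }
        )
    classification = classify_kinetics(fits, lag_threshold) if fits else "indeterminate"
    for row in kin_rows:
        row["class"] = classification

    structure_summary, traj = _structure_stage(config, seed)

    out = outdir or config.get("outdir")
    report = RunReport(
        config_hash=chash,
        seed=seed,
        classification=classification,
        ss_table=ss_rows,
        marker_table=marker_rows,
        kinetics_table=kin_rows,
        structure_summary=structure_summary,
        outdir=str(out) if out else None,
    )

    if out:
        outpath = Path(out)
        outpath.mkdir(parents=True, exist_ok=True)
        _write_csv(outpath / "secondary_structure.csv", chash,
                   ["time_h", "alpha", "beta_sheet", "beta_turn", "coil"], ss_rows)
        _write_csv(outpath / "markers.csv", chash,
                   ["marker", "time_h", "value", "sigma"], marker_rows)
        if kin_rows:
            _write_csv(outpath / "kinetics.csv", chash,
                       ["marker", "y0", "ymax", "k", "t50", "lag", "r2",
                        "converged", "direction", "class"], kin_rows)
        for s in processed:
            buf = io.StringIO()
            write_spectrum(s, buf)
            name = f"spectrum_{(s.meta.sample_id or 'sample')}.txt".replace("/", "_")
            (outpath / name).write_text(f"# config={chash}\n" + buf.getvalue())
        if truths is not None:
            (outpath / "ground_truth.json").write_text(ground_truth_json(truths))
        if traj is not None:
            with open(outpath / "dimer_trajectory.pdb", "w") as fh:
                write_structure(traj, fh)
        (outpath / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        (outpath / "summary.txt").write_text(_summary_text(report))
    return report


def _summary_text(report: RunReport) -> str:
    lines = [
        f"ramagg {__version__} run summary (config {report.config_hash}, seed {report.seed})",
        "",
        "Secondary structure (%) by time point:",
        "  time_h   alpha  beta_sheet  beta_turn   coil",
    ]
    for row in report.ss_table:
        lines.append(
            f"  {row['time_h']:6.1f}  {row['alpha']:6.2f}  {row['beta_sheet']:10.2f}"
            f"  {row['beta_turn']:9.2f}  {row['coil']:5.2f}"
        )
    lines += ["", f"Kinetic classification: {report.classification}", ""]
    if report.kinetics_table:
        lines.append("Sigmoid fits (converged markers):")
        for row in report.kinetics_table:
            if row["converged"]:
                lines.append(
                    f"  {row['marker']:>16s}: t50={row['t50']:.1f} h,"
                    f" k={row['k']:.3f} /h, lag={row['lag']:.1f} h, r2={row['r2']:.3f}"
                )
    if report.structure_summary:
        s = report.structure_summary
        lines += [
            "",
            "Structure stage:",
            f"  COM distance {s['com_first_A']:.2f} -> {s['com_last_A']:.2f} A"
            f" over {s['n_frames']} frames",
            f"  final-frame contacts: {s['final_interactions']}",
        ]
    return "\n".join(lines) + "\n"
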