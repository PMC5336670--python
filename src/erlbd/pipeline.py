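"""The two end-to-end workflows behind the command line.

``run_errorcal`` — model-error calibration: either consume a CSV of
precomputed (similarity, RMSD) points, or compute both quantities from
per-species model/crystal-structure PDB pairs plus a template sequence,
then fit the trend line, report both R² conventions, and predict the
error at requested similarities (flagging extrapolation).

``run_pocket`` — binding-site characterization of a receptor/ligand
pair: pocket residues, hydrogen bonds, van der Waals contacts and the
occlusion score.

Reports are plain dictionaries, serialized deterministically (sorted
keys, no timestamps) with the package version and a hash of the
resolved configuration embedded, so identical runs produce identical
bytes.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, fields

from . import __version__
from .align import align_global
from .errormodel import (
    CalibrationPoint,
    er_lbd_calibration,
    fit_error_model,
    loo_validate,
    predict,
    r_squared,
    read_calibration_csv,
    write_calibration_csv,
)
from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .pocket import analyze_pocket
from .structures import SequenceRecord, read_fasta, read_pdb

log = logging.getLogger(__name__)

WORKFLOWS = ("errorcal", "pocket", "synth")


@dataclass
class PipelineConfig:
    """Flat, serializable configuration for a pipeline run.

    Unknown keys are rejected by :meth:`from_mapping`; the mapping/
    dataclass round trip is lossless.
    """

    workflow: str = "errorcal"
    # errorcal inputs (mode a: CSV; mode b: structure pairs + template)
    calibration: str | None = None
    pairs: str | None = None
    template: str | None = None
    selection: str = "CA"
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    predict_similarity: tuple = ()
    r2_mode: str = "both"
    include_anchor: bool = True
    # pocket inputs
    receptor: str | None = None
    ligand: str | None = None
    pocket_cutoff: float = 4.5
    hbond_dmax: float = 3.5
    hbond_angle_min: float = 120.0
    vdw_slack: float = 0.5
    probe_radius: float = 1.4
    n_directions: int = 512
    occlusion_origin: str = "centroid"
    # generic
    out_dir: str | None = None
    plot: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        if cfg.workflow not in WORKFLOWS:
            raise ConfigurationError(f"unknown workflow {cfg.workflow!r}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["predict_similarity"] = list(self.predict_similarity)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _report_header(config: PipelineConfig) -> dict:
    return {"version": __version__, "config_hash": config.config_hash()}


def _dump_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# errorcal


def _points_from_structures(config: PipelineConfig) -> list[CalibrationPoint]:
    """Compute (similarity, RMSD) per species from structure pairs.

    The pairs file is a TSV with columns label, model_pdb, crystal_pdb.
    Similarity is model sequence vs the template sequence; RMSD is the
    superposed model-vs-crystal deviation over the selected atoms, with
    correspondence from a model/crystal sequence alignment.
    """
    from .superpose import superpose_structures

    if config.template is None:
        raise ConfigurationError("from-structures mode requires a template sequence")
    template = _read_template(config.template)
    points: list[CalibrationPoint] = []
    with open(config.pairs) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise ValidationError(
                    f"pairs file row must be label<TAB>model<TAB>crystal: {row!r}"
                )
            label, model_path, ref_path = (c.strip() for c in row)
            base = os.path.dirname(os.path.abspath(config.pairs))
            model = read_pdb(os.path.join(base, model_path) if not os.path.isabs(model_path) else model_path)
            ref = read_pdb(os.path.join(base, ref_path) if not os.path.isabs(ref_path) else ref_path)
            sim_aln = align_global(
                SequenceRecord(label, model.sequence()),
                template,
                matrix=config.matrix,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            )
            pair_aln = align_global(
                SequenceRecord(label, model.sequence()),
                SequenceRecord(label + "_ref", ref.sequence()),
                matrix=config.matrix,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            )
            fit, _ = superpose_structures(model, ref, pair_aln, selection=config.selection)
            log.info(
                "%s: similarity %.1f%%, rmsd %.3f Å over %d pairs",
                label, sim_aln.similarity_pct, fit.rmsd, fit.n_pairs,
            )
            points.append(CalibrationPoint(label, sim_aln.similarity_pct, fit.rmsd))
    if not points:
        raise InsufficientDataError("pairs file contains no usable rows")
    return points


def _read_template(path: str) -> SequenceRecord:
    if path.lower().endswith((".fasta", ".fa", ".faa")):
        return read_fasta(path)[0]
    structure = read_pdb(path)
    return SequenceRecord(structure.label or "template", structure.sequence())


def run_errorcal(config: PipelineConfig) -> dict:
    """Fit the similarity-vs-RMSD trend line and predict model errors."""
    if config.calibration and config.pairs:
        raise ConfigurationError(
            "give either a calibration CSV or a structure pairs file, not both"
        )
    if config.calibration:
        points = read_calibration_csv(config.calibration)
    elif config.pairs:
        points = _points_from_structures(config)
    else:
        log.info("no input given; using the packaged ER LBD calibration table")
        points = er_lbd_calibration()

    if not config.include_anchor:
        points = [
            p for p in points
            if not (p.is_measured and p.similarity_pct == 100.0 and p.rmsd_A == 0.0)
        ]

    model = fit_error_model(points)
    log.info(
        "fit: slope %.4f Å/%%, intercept %.3f Å over %d points",
        model.slope, model.intercept, model.n_points,
    )

    r2 = {"calibration_only": r_squared(model, points, "calibration_only")}
    if config.r2_mode in ("with_predictions", "both"):
        r2["with_predictions"] = r_squared(model, points, "with_predictions")

    targets = list(config.predict_similarity)
    targets += [
        p.similarity_pct for p in points
        if not p.is_measured and p.similarity_pct not in targets
    ]
    predictions = []
    for s in targets:
        pr = predict(model, s)
        predictions.append(
            {
                "similarity_pct": pr.similarity_pct,
                "rmsd_A": pr.rmsd_A,
                "raw_rmsd_A": pr.raw_rmsd_A,
                "extrapolated": pr.extrapolated,
            }
        )

    residuals = [
        {
            "label": p.label,
            "similarity_pct": p.similarity_pct,
            "observed_rmsd_A": p.rmsd_A,
            "fitted_rmsd_A": model.line(p.similarity_pct),
            "residual_A": p.rmsd_A - model.line(p.similarity_pct),
        }
        for p in points
        if p.is_measured
    ]

    report = {
        **_report_header(config),
        "workflow": "errorcal",
        "n_calibration_points": model.n_points,
        "slope_A_per_pct": model.slope,
        "intercept_A": model.intercept,
        "similarity_range": list(model.similarity_range),
        "r_squared": r2,
        "predictions": predictions,
        "residuals": residuals,
    }
    if len([p for p in points if p.is_measured]) >= 3:
        loo = loo_validate(points)
        report["loo_mean_abs_error_A"] = float(loo["abs_error"].mean(skipna=True))

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        _dump_json(report, os.path.join(config.out_dir, "error_model.json"))
        write_calibration_csv(points, os.path.join(config.out_dir, "calibration.csv"))
        if config.plot:
            _plot_errorcal(points, model, predictions,
                           os.path.join(config.out_dir, "calibration.png"))
    return report


def _plot_errorcal(points, model, predictions, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [p.similarity_pct for p in points if p.is_measured]
    ys = [p.rmsd_A for p in points if p.is_measured]
    ax.scatter(xs, ys, label="calibration", zorder=3)
    for pr in predictions:
        ax.scatter([pr["similarity_pct"]], [pr["rmsd_A"]], marker="s",
                   label="predicted", zorder=3)
    grid_lo = min(xs + [pr["similarity_pct"] for pr in predictions]) - 5
    grid = [grid_lo, 105]
    ax.plot(grid, [model.line(g) for g in grid], "--", label="trend line")
    ax.set_xlabel("sequence similarity vs template (%)")
    ax.set_ylabel("model RMSD (Å)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pocket


def run_pocket(config: PipelineConfig) -> dict:
    """Characterize a receptor/ligand binding site."""
    if not config.receptor:
        raise ConfigurationError("pocket workflow requires a receptor PDB")
    receptor_all = read_pdb(config.receptor)
    if config.ligand:
        from .structures import Structure

        ligand = read_pdb(config.ligand)
        receptor = Structure(
            [a for a in receptor_all.atoms if not a.is_hetero],
            label=receptor_all.label,
        )
    else:
        from .structures import Structure

        het = receptor_all.hetero_atoms()
        if not het:
            raise ValidationError(
                "no ligand atoms found: receptor file has no HETATM records "
                "and no separate ligand file was given"
            )
        ligand = Structure(het, label="ligand")
        receptor = Structure(
            [a for a in receptor_all.atoms if not a.is_hetero],
            label=receptor_all.label,
        )
    report_obj = analyze_pocket(
        receptor,
        ligand,
        cutoff=config.pocket_cutoff,
        hbond_d_max=config.hbond_dmax,
        hbond_angle_min=config.hbond_angle_min,
        vdw_slack=config.vdw_slack,
        probe_radius=config.probe_radius,
        n_directions=config.n_directions,
        seed=config.seed,
        occlusion_origin=config.occlusion_origin,
    )
    report = {
        **_report_header(config),
        "workflow": "pocket",
        "pocket_residues": [str(r) for r in report_obj.pocket_residues],
        "n_hbonds": len(report_obj.hbonds),
        "n_vdw_contacts": len(report_obj.vdw_contacts),
        "contacts": [
            {
                "receptor_atom": str(c.receptor_atom),
                "ligand_atom": str(c.ligand_atom),
                "distance_A": round(c.distance, 3),
                "kind": c.kind,
                "angle_deg": None if c.angle is None else round(c.angle, 1),
            }
            for c in report_obj.contacts
        ],
        "occlusion_score": report_obj.occlusion,
        "occlusion_origin": report_obj.occlusion_origin,
        "parameters": report_obj.parameters,
    }
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        _dump_json(report, os.path.join(config.out_dir, "pocket.json"))
        with open(os.path.join(config.out_dir, "pocket.txt"), "w") as fh:
            fh.write(format_pocket_table(report))
    return report


def format_pocket_table(report: dict) -> str:
    lines = [
        f"pocket residues ({len(report['pocket_residues'])}): "
        + ", ".join(report["pocket_residues"]),
        f"hydrogen bonds: {report['n_hbonds']}",
        f"van der Waals contacts: {report['n_vdw_contacts']}",
        "",
        f"{'kind':6s} {'receptor':>18s} {'ligand':>14s} {'d (Å)':>7s} {'angle':>7s}",
    ]
    for c in report["contacts"]:
        angle = "-" if c["angle_deg"] is None else f"{c['angle_deg']:.1f}"
        lines.append(
            f"{c['kind']:6s} {c['receptor_atom']:>18s} {c['ligand_atom']:>14s} "
            f"{c['distance_A']:7.3f} {angle:>7s}"
        )
    lines.append("")
    lines.append(
        f"occlusion score ({report['occlusion_origin']}): "
        f"{report['occlusion_score']:.3f}  (0 = open, 1 = enclosed)"
    )
    return "\n".join(lines) + "\n"
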