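"""End-to-end orchestration: catalogue → windows → motif scan → enrichment.

Driven by a YAML config; every run writes TSV reports plus a JSON manifest
recording the config snapshot, seed, input digests and per-stage counts, so
each reported number is traceable to its inputs.  Reruns with the same seed
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .catalog import Annotation, ConfigError, deduplicate, filter_records, parse_catalog
from .context import StrandMode, WindowSpec, audit_ref_alleles, extract_windows, load_reference
from .domains import CdsMap, DomainAnnotation, domain_track, render_track
from .enrichment import build_contingency, compare_control, fisher_exact, inheritance_summary, sex_summary
from .motifs import Correction, MotifSpec, NullModel, PermutationConfig, Statistic, scan_all_motifs

__all__ = ["PipelineError", "run_pipeline", "load_config"]


class PipelineError(Exception):
    """Raised with a stage tag when any pipeline stage fails."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _get(cfg: Mapping, dotted: str, default=None, required: bool = False):
    node: Any = cfg
    for part in dotted.split("."):
        if not isinstance(node, Mapping) or part not in node:
            if required:
                raise ConfigError(f"config key {dotted!r} is required")
            return default
        node = node[part]
    return node


def run_pipeline(
    config: str | Path | Mapping,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    dedup: bool | None = None,
    allow_ref_mismatch: bool = False,
) -> dict:
    """Run the full analysis described by a config mapping or YAML path.

    Returns the manifest dict.  On any stage failure the partially written
    output files are removed and a :class:`PipelineError` is raised.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out = Path(out_dir or _get(cfg, "output.dir", "hotspot_out"))
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(cfg, out, seed, dedup, allow_ref_mismatch, written)
    except (PipelineError, ConfigError):
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("internal", str(exc)) from exc


def _write_tsv(path: Path, header: list[str], rows: list[list], written: list[Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    written.append(path)


def _run(cfg, out, seed, dedup, allow_ref_mismatch, written) -> dict:
    # --- inputs ---------------------------------------------------------
    try:
        cat_path = Path(_get(cfg, "catalog.path", required=True))
        records = parse_catalog(cat_path, _get(cfg, "catalog.dialect", "tsv"))
    except ConfigError:
        raise
    except Exception as exc:
        raise PipelineError("catalog", str(exc)) from exc
    if not records:
        raise PipelineError("catalog", "catalogue is empty")

    try:
        ref_path = Path(_get(cfg, "reference.path", required=True))
        ref = load_reference(
            ref_path,
            _get(cfg, "reference.contig"),
            int(_get(cfg, "reference.offset", 1)),
            _get(cfg, "reference.build", ""),
        )
    except ConfigError:
        raise
    except Exception as exc:
        raise PipelineError("reference", str(exc)) from exc

    # --- windows --------------------------------------------------------
    try:
        window_spec = WindowSpec(
            flank=int(_get(cfg, "window.flank", 5)),
            strand_mode=StrandMode(_get(cfg, "window.strand_mode", "REFERENCE_ONLY").upper()),
        )
        mismatches = audit_ref_alleles(ref, records)
        if mismatches and not allow_ref_mismatch:
            raise PipelineError(
                "audit",
                f"{len(mismatches)} catalogue ref allele(s) disagree with the reference "
                f"(first few: {mismatches[:5]}); rerun with allow_ref_mismatch to override",
            )
        n_input = len(records)
        unique, summary = deduplicate(records)
        use_dedup = bool(dedup if dedup is not None else _get(cfg, "catalog.dedup", False))
        analyzed = unique if use_dedup else records
        windows = extract_windows(ref, analyzed, window_spec)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("windows", str(exc)) from exc

    # --- motif scan -----------------------------------------------------
    try:
        motif_spec = MotifSpec(
            length_l=int(_get(cfg, "motif.length", 3)),
            statistic=Statistic(_get(cfg, "motif.statistic", "WINDOWS_WITH_HIT").upper()),
        )
        perm = PermutationConfig(
            n_iterations=int(_get(cfg, "perm.iterations", 10_000)),
            null_model=NullModel(_get(cfg, "perm.null_model", "POSITIONAL_RESAMPLE").upper()),
            seed=int(seed if seed is not None else _get(cfg, "perm.seed", 0)),
            alpha=float(_get(cfg, "perm.alpha", 0.05)),
            correction=Correction(_get(cfg, "perm.correction", "BONFERRONI").upper()),
        )
        mask = None
        if _get(cfg, "perm.mask_bed"):
            from .context import bed_mask_positions

            mask = bed_mask_positions(Path(_get(cfg, "perm.mask_bed")), ref.contig)
        results = scan_all_motifs(
            ref, windows, perm, motif_spec, window_spec, window_spec.strand_mode,
            position_mask=mask,
        )
        _write_tsv(
            out / "motif_scan.tsv",
            ["motif", "observed", "p_empirical", "p_display", "p_corrected", "significant"],
            [
                [r.motif, r.observed, f"{r.p_empirical:.6g}", r.p_display, f"{r.p_corrected:.6g}", r.significant]
                for r in results
            ],
            written,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("motif_scan", str(exc)) from exc

    # --- enrichment around the focal motif ------------------------------
    try:
        focal = _get(cfg, "report.focal_motif") or results[0].motif
        if len(focal) != motif_spec.length_l or set(focal) - set("ACGT"):
            raise PipelineError(
                "enrichment",
                f"focal motif {focal!r} is not an ACGT string of length {motif_spec.length_l}",
            )
        from .motifs import observed_statistic

        _, flagged_ids = observed_statistic(windows, focal, motif_spec, window_spec.strand_mode)
        table = build_contingency(analyzed, flagged_ids)
        enr = fisher_exact(table)
        _write_tsv(
            out / "enrichment.tsv",
            ["focal_motif", "a_flag_splice", "b_flag_other", "c_unflag_splice", "d_unflag_other",
             "n_unknown_annot", "p_fisher_two_sided", "odds_ratio", "odds_ratio_haldane",
             "flagged_splicing_fraction", "overall_splicing_fraction"],
            [[focal, table.a, table.b, table.c, table.d, table.n_unknown_annotation,
              f"{enr.p_two_sided:.6g}", f"{enr.odds_ratio:.6g}", f"{enr.odds_ratio_haldane:.6g}",
              f"{enr.flagged_splicing_fraction:.6g}", f"{enr.overall_splicing_fraction:.6g}"]],
            written,
        )

        flagged_records = [r for r in analyzed if r.id in flagged_ids]
        sx = sex_summary(flagged_records)
        inh = inheritance_summary(analyzed, flagged_ids, by_annotation=Annotation.SPLICING)
        rows = [["sex", "F", sx.n_female], ["sex", "M", sx.n_male], ["sex", "UNKNOWN", sx.n_unknown],
                ["sex", "female_fraction_of_known",
                 "NA" if sx.female_fraction_of_known is None else f"{sx.female_fraction_of_known:.6g}"]]
        for cls, n in inh.flagged.items():
            rows.append(["inheritance_flagged_splicing", cls.value, n])
        for cls, n in inh.unflagged.items():
            rows.append(["inheritance_unflagged_splicing", cls.value, n])
        _write_tsv(out / "sex_inheritance.tsv", ["section", "key", "value"], rows, written)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("enrichment", str(exc)) from exc

    # --- optional control comparison ------------------------------------
    control_summary = None
    if _get(cfg, "control.path"):
        try:
            ctl_records = parse_catalog(Path(_get(cfg, "control.path")), _get(cfg, "control.dialect", "tsv"))
            ctl_windows = extract_windows(ref, ctl_records, window_spec)
            cmp_res = compare_control(windows, ctl_windows, focal, perm, window_spec.strand_mode)
            control_summary = dataclasses.asdict(cmp_res)
            _write_tsv(
                out / "control_comparison.tsv",
                ["focal_motif", "case_fraction", "control_fraction", "difference", "p_value"],
                [[focal, f"{cmp_res.case_fraction:.6g}", f"{cmp_res.control_fraction:.6g}",
                  f"{cmp_res.difference:.6g}", f"{cmp_res.p_value:.6g}"]],
                written,
            )
        except Exception as exc:
            raise PipelineError("control", str(exc)) from exc

    # --- optional domain track ------------------------------------------
    if _get(cfg, "domains.table"):
        try:
            domains = [DomainAnnotation(d["name"], int(d["start_aa"]), int(d["end_aa"]))
                       for d in _get(cfg, "domains.table")]
            cds = CdsMap(tuple(
                (int(s["g_start"]), int(s["g_end"]), int(s["aa_start"]))
                for s in _get(cfg, "domains.cds_map", [])
            ))
            counts = domain_track(analyzed, flagged_ids, domains, cds,
                                  multiplicity=summary.recurrence_multiplicity)
            _write_tsv(
                out / "domain_track.tsv",
                ["domain", "n_total", "n_flagged", "n_total_weighted", "n_flagged_weighted"],
                [[c.name, c.n_total, c.n_flagged, f"{c.n_total_weighted:g}", f"{c.n_flagged_weighted:g}"]
                 for c in counts],
                written,
            )
            (out / "domain_track.txt").write_text(render_track(counts) + "\n")
            written.append(out / "domain_track.txt")
        except ConfigError as exc:
            raise PipelineError("domains", str(exc)) from exc
        except Exception as exc:
            raise PipelineError("domains", str(exc)) from exc

    # --- manifest --------------------------------------------------------
    manifest = {
        "tool": "motifhotspot",
        "version": __version__,
        "config": cfg,
        "seed": perm.seed,
        "inputs": {
            "catalog": {"path": str(cat_path), "sha256": _sha256(cat_path)},
            "reference": {"path": str(ref_path), "sha256": _sha256(ref_path)},
        },
        "counts": {
            "n_records": n_input,
            "n_unique": summary.n_unique,
            "n_unique_snv": summary.n_unique_snv,
            "n_unique_indel": summary.n_unique_indel,
            "n_analyzed": len(analyzed),
            "deduplicated": use_dedup,
            "n_flagged_focal": len(flagged_ids),
        },
        "focal_motif": focal,
        "top_motifs": [
            {"motif": r.motif, "observed": r.observed, "p_empirical": r.p_empirical,
             "p_display": r.p_display, "p_corrected": r.p_corrected, "significant": r.significant}
            for r in results[:5]
        ],
        "enrichment": {
            "table": [table.a, table.b, table.c, table.d],
            "p_two_sided": enr.p_two_sided,
            "odds_ratio": enr.odds_ratio,
            "odds_ratio_haldane": enr.odds_ratio_haldane,
        },
        "control": control_summary,
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written.append(manifest_path)
    return manifest
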