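"""End-to-end comparison pipeline and report rendering.

One :func:`run_pipeline` call builds (or loads) cellulose Ibeta and II
crystals over a range of chain lengths, decomposes their interchain and
intrachain nonbonded energies over the central chains, extracts bulk
energies per glucose unit by linear fitting, tabulates hydrogen bonds in
both group scoring modes, and reports the hydrogen-bond share of the
interchain electrostatics.  The run configuration is echoed into every
report so that the detection criteria and force-field variant in effect are
always auditable.  Identical configurations yield byte-identical JSON
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bulk as bulkmod
from . import crystal as crystalmod
from . import energetics, hbond as hbondmod
from .forcefield import assign_parameters, load_forcefield, neutralize_termini, variant_by_name

__all__ = ["RunConfig", "run_pipeline", "render_report"]

log = logging.getLogger("cellenergy")

_FORMS = ("Ibeta", "II")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Defaults follow the reference study conditions: 52-chain crystals of 6-,
    8-, 10- and 12-mers with 30 central chains.  Smaller values are useful
    for quick runs and testing.
    """

    variant: str = "GLYCAM06_OSMOr14_TIP5P"
    n_chains: int = 52
    dp_list: tuple[int, ...] = (6, 8, 10, 12)
    n_central: int = 30
    max_d_HO: float = 3.0
    min_angle: float = 115.0
    include_intrachain: bool = False
    forms: tuple[str, ...] = _FORMS
    seed: int = 0

    def validate(self) -> None:
        variant_by_name(self.variant)  # raises on unknown variant
        if self.n_central > self.n_chains:
            raise ValueError("n_central cannot exceed n_chains")
        if len(self.dp_list) < 2:
            raise ValueError("need at least two chain lengths for bulk fits")
        if any(dp < 2 for dp in self.dp_list):
            raise ValueError("all dp values must be >= 2")
        for f in self.forms:
            if f not in _FORMS:
                raise ValueError(f"unknown crystal form {f!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("dp_list", "forms"):
            if k in doc:
                doc[k] = tuple(doc[k])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dp_list"] = list(self.dp_list)
        d["forms"] = list(self.forms)
        return d


def _analyze_form(cfg: RunConfig, form: str) -> dict:
    ff = load_forcefield(cfg.variant)
    criteria = hbondmod.HBondCriteria(cfg.max_d_HO, cfg.min_angle)
    inter_reports_e: list[tuple[int, energetics.EnergyBreakdown]] = []
    intra_reports: list[tuple[int, energetics.EnergyBreakdown]] = []
    largest = None
    for dp in sorted(cfg.dp_list):
        cr = crystalmod.build_crystal(form, cfg.n_chains, dp)
        pc = neutralize_termini(assign_parameters(cr, ff))
        central = crystalmod.select_central_chains(cr, cfg.n_central)
        log.info(
            "form=%s dp=%d: %d chains, %d atoms, %d central chains, variant=%s",
            form, dp, cr.n_chains, cr.n_atoms, len(central), cfg.variant,
        )
        br = energetics.interchain_energy(pc, central)
        inter_reports_e.append((dp, br))
        if cfg.include_intrachain:
            intra_reports.append((dp, energetics.intrachain_nonbonded_energy(pc, central)))
        largest = (cr, pc, central)
    series_e = bulkmod.assemble_size_series(
        inter_reports_e, "electrostatic", term="electrostatic interchain", variant=cfg.variant
    )
    series_v = bulkmod.assemble_size_series(
        inter_reports_e, "vdw", term="vdW interchain", variant=cfg.variant
    )
    fit_e = bulkmod.fit_bulk_energy(series_e)
    fit_v = bulkmod.fit_bulk_energy(series_v)

    cr, pc, central = largest
    parities = crystalmod.classify_chain_parity(cr)
    bonds = hbondmod.detect_hbonds(pc, criteria, parity_labels=parities)
    central_set = set(central)
    bonds = [b for b in bonds if b.donor_chain in central_set]
    table_rows = []
    energies = {m: [hbondmod.hbond_energy(pc, b, m) for b in bonds] for m in ("COH_O", "COH_COX")}
    for cls_label in sorted({b.class_label for b in bonds}):
        sel = [i for i, b in enumerate(bonds) if b.class_label == cls_label]
        row = {
            "class": cls_label,
            "n": len(sel),
            "d_HO": float(np.mean([bonds[i].d_HO for i in sel])),
            "d_OO": float(np.mean([bonds[i].d_OO for i in sel])),
            "angle": float(np.mean([bonds[i].angle for i in sel])),
        }
        for m in ("COH_O", "COH_COX"):
            row[f"elec_{m}"] = float(np.mean([energies[m][i].electrostatic for i in sel]))
            row[f"vdw_{m}"] = float(np.mean([energies[m][i].vdw for i in sel]))
        table_rows.append(row)

    per_glucose = {}
    fraction = {}
    inter_bonds = [b for b in bonds if b.scope == "inter"]
    for m in ("COH_O", "COH_COX"):
        if inter_bonds and all(b.donor_parity in ("origin", "center") for b in inter_bonds):
            pg = hbondmod.aggregate_per_glucose(pc, bonds, "inter", m)
            per_glucose[m] = pg
            if fit_e.slope != 0:
                fraction[m] = hbondmod.fraction_of_interchain_electrostatics(pg, fit_e.slope)

    result = {
        "bulk": {
            "electrostatic_interchain": dataclasses.asdict(fit_e),
            "vdw_interchain": dataclasses.asdict(fit_v),
        },
        "series": {
            "electrostatic_interchain": dataclasses.asdict(series_e),
            "vdw_interchain": dataclasses.asdict(series_v),
        },
        "hbond_table": table_rows,
        "hbond_per_glucose_inter": per_glucose,
        "hbond_fraction_of_interchain_electrostatics_percent": fraction,
    }
    if cfg.include_intrachain:
        s_ie = bulkmod.assemble_size_series(
            intra_reports, "electrostatic", term="electrostatic intrachain (nonbonded)",
            variant=cfg.variant,
        )
        s_iv = bulkmod.assemble_size_series(
            intra_reports, "vdw", term="vdW intrachain (nonbonded)", variant=cfg.variant
        )
        result["bulk"]["electrostatic_intrachain_nonbonded"] = dataclasses.asdict(
            bulkmod.fit_bulk_energy(s_ie)
        )
        result["bulk"]["vdw_intrachain_nonbonded"] = dataclasses.asdict(
            bulkmod.fit_bulk_energy(s_iv)
        )
    return result


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full comparison and return the report bundle (JSON-ready)."""
    cfg.validate()
    bundle = {"config": cfg.to_dict(), "forms": {}}
    for form in cfg.forms:
        try:
            bundle["forms"][form] = _analyze_form(cfg, form)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed for form {form!r}: {exc}") from exc
    return bundle


def _nan_to_none(obj):
    if isinstance(obj, float):
        return None if not np.isfinite(obj) else obj
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_nan_to_none(v) for v in obj]
    return obj


def render_report(bundle: dict, fmt: str, out_dir: str | Path) -> list[Path]:
    """Write the bundle as ``json`` (full precision), ``csv`` tables, or a
    ``markdown`` summary with energies at one decimal (kcal/mol)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "json":
        p = out_dir / "report.json"
        p.write_text(json.dumps(_nan_to_none(bundle), indent=2, sort_keys=True) + "\n")
        written.append(p)
    elif fmt == "csv":
        for form, res in bundle.get("forms", {}).items():
            rows = res.get("hbond_table", [])
            p = out_dir / f"hbonds_{form}.csv"
            cols = ["class", "n", "d_HO", "d_OO", "angle",
                    "elec_COH_O", "elec_COH_COX", "vdw_COH_O", "vdw_COH_COX"]
            pd.DataFrame(rows, columns=cols).to_csv(p, index=False)
            written.append(p)
            brows = []
            for term, fit in res.get("bulk", {}).items():
                brows.append({"term": term, **fit})
            p = out_dir / f"bulk_{form}.csv"
            pd.DataFrame(brows).to_csv(p, index=False)
            written.append(p)
    elif fmt == "markdown":
        p = out_dir / "report.md"
        lines = ["# Cellulose crystal energetics report", ""]
        lines.append(f"Configuration: `{json.dumps(bundle.get('config', {}), sort_keys=True)}`")
        for form, res in bundle.get("forms", {}).items():
            lines += ["", f"## {form}", "", "### Bulk energies per glucose unit (kcal/mol)", ""]
            for term, fit in res.get("bulk", {}).items():
                se = fit["slope_stderr"]
                se_txt = f" ± {se:.1f}" if se == se else ""
                lines.append(f"- {term}: {fit['slope']:.1f}{se_txt}")
            tab = res.get("hbond_table", [])
            if tab:
                lines += ["", "### Hydrogen bonds", "",
                          "| class | n | d_HO | d_OO | angle | COH-O | COH-COX | vdW COH-O | vdW COH-COX |",
                          "|---|---|---|---|---|---|---|---|---|"]
                for r in tab:
                    lines.append(
                        "| {class} | {n} | {d_HO:.2f} | {d_OO:.2f} | {angle:.0f} "
                        "| {elec_COH_O:.1f} | {elec_COH_COX:.1f} "
                        "| {vdw_COH_O:.1f} | {vdw_COH_COX:.1f} |".format(**r)
                    )
            pg = res.get("hbond_per_glucose_inter", {})
            if pg:
                lines += ["", "### Interchain hydrogen-bond energy per glucose unit", ""]
                for m, v in pg.items():
                    lines.append(f"- {m}: {v:.1f} kcal/mol")
            fr = res.get("hbond_fraction_of_interchain_electrostatics_percent", {})
            for m, v in fr.items():
                lines.append(f"- {m} share of interchain electrostatics: {v}%")
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    else:
        raise ValueError(f"unsupported report format {fmt!r}")
    return written
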