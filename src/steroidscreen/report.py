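"""Human-readable summaries of an analysis bundle.

Emits a QC summary (one row per criterion), a classification table shaped
like the per-chemical effect/LOEC comparison tables, and a metrics table
for the confusion-matrix evaluation.  Concentrations are printed in μM on
the way out (everything internal is mol/L).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .evaluate import performance_report
from .pipeline import AnalysisBundle, classification_to_dict

__all__ = ["qc_table", "classification_table", "metrics_table", "write_report"]


def _um(conc_m: float | None) -> float | None:
    return None if conc_m is None else conc_m * 1e6


def qc_table(bundle: AnalysisBundle) -> pd.DataFrame:
    rows = []
    for family in ("estrogens", "androgens"):
        fam = bundle.qc[family]
        for name, chk in fam["checks"].items():
            rows.append({
                "family": fam["family"], "criterion": name,
                "value": chk["value"], "threshold": chk["threshold"],
                "direction": chk["direction"], "passed": chk["passed"],
            })
        for rep, info in fam["replicates"].items():
            for name, chk in info["checks"].items():
                rows.append({
                    "family": fam["family"], "criterion": f"{name}[rep{rep}]",
                    "value": chk["value"], "threshold": chk["threshold"],
                    "direction": chk["direction"], "passed": chk["passed"],
                })
    for name, chk in bundle.qc.get("controls", {}).items():
        rows.append({
            "family": "controls", "criterion": name, "value": chk["value"],
            "threshold": chk["threshold"], "direction": chk["direction"],
            "passed": chk["passed"],
        })
    return pd.DataFrame(rows)


def classification_table(bundle: AnalysisBundle) -> pd.DataFrame:
    d = classification_to_dict(bundle.classification)
    rows = []
    for family in ("androgens", "estrogens"):
        fc = d["families"].get(family)
        if fc is None:
            continue
        direct = (d["direct_antiandrogenicity"] if family == "androgens"
                  else d["direct_estrogenicity"])
        loec = _um(fc["loec_h295r"])
        if loec is None and fc["apparent_loec"] is not None:
            loec_str = f"({_um(fc['apparent_loec']):g})"
        else:
            loec_str = "nd" if loec is None else f"{loec:g}"
        rows.append({
            "chemical": d["chemical_id"],
            "family": family,
            "effect": fc["effect"],
            "loec_um_h295r": loec_str,
            "direct_loec_um_calux": ("nd" if not direct["present"]
                                     else f"{_um(direct['loec_calux']):g}"),
            "masked_by": fc["masked_by"],
            "notes": fc["notes"],
        })
    return pd.DataFrame(rows)


def metrics_table(report: dict | None = None) -> pd.DataFrame:
    """Metrics triplets per family and comparison (rounded to 2 decimals)."""
    from .evaluate import load_reference_records
    if report is None:
        report = performance_report(load_reference_records())
    rows = []
    for family, comps in report.items():
        for comp, d in comps.items():
            rows.append({
                "family": family, "comparison": comp, **d["matrix"],
                **{k: ("" if v is None else v) for k, v in d["metrics"].items()},
            })
    return pd.DataFrame(rows)


def write_report(bundle: AnalysisBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc_table(bundle).to_csv(out / "qc_summary.csv", index=False)
    cls = classification_table(bundle)
    cls.to_csv(out / "classification.csv", index=False)
    (out / "bundle.json").write_text(bundle.to_json())
    lines = [f"# Analysis report: {bundle.chemical_id}", ""]
    lines.append("## Classification")
    lines.append("```\n" + (cls.to_string(index=False) if len(cls) else "(empty)") + "\n```")
    lines.append("")
    lines.append("## QC verdicts")
    for family in ("estrogens", "androgens"):
        fam = bundle.qc[family]
        lines.append(f"- {fam['family']}: {fam['verdict']}"
                     + (f" (tolerated: {', '.join(fam['tolerated_criteria'])})"
                        if fam["tolerated_criteria"] else ""))
    lines.append(f"- excluded replicates: {bundle.excluded_bio_reps}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
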