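"""Machine-readable report writers (CSV mirrors of the result tables + JSON).

CSV bodies are deterministic for identical inputs: floats are printed with 4
decimals (matching the precision convention of the result tables) and the
run timestamp lives only in the JSON metadata block.  The JSON twin carries
full-precision values.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .qspr_stats import PROPERTY_FIELDS, QsprReport
from .topo_indices import INDEX_FIELDS, IndexSet

__all__ = ["ReportBundle", "write_indices_csv", "write_report_bundle"]


@dataclass
class ReportBundle:
    """Everything one pipeline run produced."""

    indices_table: list[tuple[str, IndexSet]]
    qspr: Optional[QsprReport] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metadata.setdefault("tool", "topoqspr")
        self.metadata.setdefault("version", __version__)
        self.metadata.setdefault(
            "timestamp", _dt.datetime.now(_dt.timezone.utc).isoformat()
        )


def _fmt(x) -> str:
    if isinstance(x, (int,)):
        return str(x)
    return f"{x:.4f}"


def write_indices_csv(rows: Sequence[tuple[str, IndexSet]], path: Path) -> None:
    lines = ["drug," + ",".join(INDEX_FIELDS)]
    for name, ix in rows:
        lines.append(name + "," + ",".join(_fmt(v) for v in ix.as_tuple()))
    Path(path).write_text("\n".join(lines) + "\n")


def _indices_json(rows: Sequence[tuple[str, IndexSet]]) -> list[dict]:
    return [{"drug": name, **ix.as_dict()} for name, ix in rows]


def _grid_csv(df, path: Path) -> None:
    lines = ["index," + ",".join(df.columns)]
    for iname in df.index:
        lines.append(
            iname + "," + ",".join(_fmt(float(df.loc[iname, c])) for c in df.columns)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _fits_csv(qspr: QsprReport, path: Path) -> None:
    header = "index,property,n,intercept_A,slope_b,pearson_r,r_squared,f_stat,p_value,see,significant"
    lines = [header]
    for iname in INDEX_FIELDS:
        for pname in PROPERTY_FIELDS:
            key = (iname, pname)
            if key not in qspr.fits:
                continue
            f = qspr.fits[key]
            lines.append(
                ",".join(
                    [
                        iname, pname, str(f.n),
                        _fmt(f.intercept_A), _fmt(f.slope_b), _fmt(f.pearson_r),
                        _fmt(f.r_squared), _fmt(f.f_stat), _fmt(f.p_value),
                        _fmt(f.see), str(f.significant).lower(),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_report_bundle(bundle: ReportBundle, out_dir: Path) -> dict[str, Path]:
    """Write every table of the bundle under out_dir; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    p = out_dir / "indices.csv"
    write_indices_csv(bundle.indices_table, p)
    written["indices_csv"] = p

    doc: dict = {
        "metadata": bundle.metadata,
        "indices": _indices_json(bundle.indices_table),
    }
    if bundle.qspr is not None:
        q = bundle.qspr
        _grid_csv(q.correlation_table, out_dir / "correlation.csv")
        written["correlation_csv"] = out_dir / "correlation.csv"
        _grid_csv(q.see_table, out_dir / "see.csv")
        written["see_csv"] = out_dir / "see.csv"
        _fits_csv(q, out_dir / "fits.csv")
        written["fits_csv"] = out_dir / "fits.csv"
        doc["qspr"] = {
            "n_molecules": q.n_molecules,
            "index_source": q.index_source,
            "warnings": q.warnings,
            "correlation": {
                i: {p_: float(q.correlation_table.loc[i, p_]) for p_ in PROPERTY_FIELDS}
                for i in INDEX_FIELDS
            },
            "see": {
                i: {p_: float(q.see_table.loc[i, p_]) for p_ in PROPERTY_FIELDS}
                for i in INDEX_FIELDS
            },
            "fits": [
                {
                    "index": i, "property": p_, "n": f.n,
                    "intercept_A": f.intercept_A, "slope_b": f.slope_b,
                    "pearson_r": f.pearson_r, "r_squared": f.r_squared,
                    "f_stat": f.f_stat, "p_value": f.p_value, "see": f.see,
                    "significant": f.significant,
                }
                for (i, p_), f in (
                    ((i, p_), q.fits[(i, p_)])
                    for i in INDEX_FIELDS
                    for p_ in PROPERTY_FIELDS
                    if (i, p_) in q.fits
                )
            ],
            "errors": {f"{i}/{p_}": msg for (i, p_), msg in q.errors.items()},
        }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(doc, indent=2) + "\n")
    written["json"] = json_path
    return written
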