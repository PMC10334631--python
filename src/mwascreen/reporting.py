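"""Volcano-plot tables and figures, signal summaries, and the run manifest.

The volcano representation plots each drug at ``x = log2(hazard ratio)``
and ``y = -log10(FDR-adjusted p)``; significant drugs are those with an
adjusted p at or below the FDR threshold, and protective vs detrimental
direction is the sign of x.  One figure/table is produced per
outcome x ATC level x stage.  Acceptance lives on the CSV tables; the
rendered figures are a convenience layer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .claims_model import ValidationError
from .screening import ScreenReport, write_results

__all__ = ["VolcanoRow", "volcano_table", "render_report"]

#: floor applied to adjusted p before the log, to avoid infinities
P_FLOOR = 1e-300


@dataclass(frozen=True)
class VolcanoRow:
    drug: str
    x: float                  # log2 hazard ratio
    y: float                  # -log10 adjusted p
    significant: bool
    direction: str            # protective iff x < 0

    def __post_init__(self):
        if self.direction != ("protective" if self.x < 0 else "detrimental"):
            raise ValidationError("direction must follow the sign of log2(HR)")


def volcano_table(
    results: pd.DataFrame,
    q: float = 0.05,
    p_floor: float = P_FLOOR,
    p_column: str = "p_fdr_adjusted",
) -> pd.DataFrame:
    """Volcano coordinates for one outcome x level x stage results slice.

    Discovery stages plot the FDR-adjusted p on the y axis; for validation
    stages (where no family-wise adjustment applies) pass
    ``p_column="p_raw"`` and the validation threshold as ``q``.  Only
    converged fits with a positive HR and a finite p are plotted (others
    are excluded with an audit note in the returned frame's ``attrs``).
    Rows come back sorted by y descending; significance is
    boundary-inclusive (``p <= q``), matching the step-up rule.
    """
    excluded: list[str] = []
    rows: list[VolcanoRow] = []
    for r in results.itertuples(index=False):
        p = getattr(r, p_column)
        if not r.converged or not np.isfinite(p):
            excluded.append(f"{r.drug}: not converged or no {p_column}")
            continue
        if not r.hr > 0:
            excluded.append(f"{r.drug}: non-positive HR")
            continue
        x = float(np.log2(r.hr))
        y = float(-np.log10(max(p, p_floor)))
        rows.append(
            VolcanoRow(
                drug=r.drug,
                x=x,
                y=y,
                significant=bool(p <= q),
                direction="protective" if x < 0 else "detrimental",
            )
        )
    frame = pd.DataFrame(
        [dataclasses.asdict(v) for v in rows],
        columns=["drug", "x", "y", "significant", "direction"],
    )
    frame = frame.sort_values(["y", "drug"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    frame.attrs["excluded"] = excluded
    return frame


def _volcano_figure(table: pd.DataFrame, title: str, q: float, path: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if len(table):
        sig = table["significant"]
        ax.scatter(table.loc[~sig, "x"], table.loc[~sig, "y"], s=18,
                   c="#9aa0a6", label="not significant")
        colors = np.where(table.loc[sig, "x"] < 0, "#1a73e8", "#d93025")
        ax.scatter(table.loc[sig, "x"], table.loc[sig, "y"], s=28, c=colors,
                   label="significant")
        for r in table.loc[sig].itertuples(index=False):
            ax.annotate(r.drug, (r.x, r.y), fontsize=8,
                        xytext=(3, 3), textcoords="offset points")
    ax.axhline(-np.log10(q), ls="--", lw=0.8, c="grey")
    ax.axvline(0.0, ls=":", lw=0.8, c="grey")
    ax.set_xlabel(r"$\log_2$ hazard ratio")
    ax.set_ylabel(r"$-\log_{10}$ FDR-adjusted p")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_report(
    report: ScreenReport,
    out_dir: str | Path,
    make_figures: bool = True,
) -> dict[str, Path]:
    """Write volcano tables (and figures), the signal summary and a manifest.

    Outputs: ``volcano_{outcome}_L{level}_{stage}.csv`` (+ ``.png``),
    ``signals.csv``, ``results.csv`` and ``manifest.json``.  Rerunning with
    identical inputs reproduces the CSV outputs byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    res = report.results
    q = report.config.fdr_q

    for (level, outcome, stage), part in sorted(
        res.groupby(["level", "outcome", "stage"], sort=True).groups.items()
    ):
        sl = res.loc[part]
        if stage == "validation":
            table = volcano_table(
                sl, q=report.config.validation_alpha, p_column="p_raw"
            )
        else:
            table = volcano_table(sl, q=q)
        name = f"volcano_{outcome}_L{level}_{stage}"
        path = out_dir / f"{name}.csv"
        out = table.copy()
        for c in ("x", "y"):
            out[c] = out[c].map(lambda v: f"{v:.12g}")
        out.to_csv(path, index=False)
        written[name] = path
        if make_figures and len(table):
            fig_path = out_dir / f"{name}.png"
            _volcano_figure(
                table, f"{outcome} mortality, ATC level {level} ({stage})",
                q, fig_path,
            )
            written[name + "_png"] = fig_path

    sig_rows = []
    for level, outcome, drug in report.discovery_signals:
        key = (level, outcome, drug)
        validated = key in set(report.validated_signals)
        disc = res.loc[
            (res["level"] == level) & (res["outcome"] == outcome)
            & (res["drug"] == drug) & (res["stage"] == "discovery")
        ].iloc[0]
        sig_rows.append(
            {
                "drug": drug,
                "level": level,
                "outcome": outcome,
                "validated": validated,
                "direction": report.directions.get(
                    key, "protective" if disc["hr"] < 1 else "detrimental"
                ),
                "hr_discovery": f"{disc['hr']:.10g}",
                "p_fdr_discovery": f"{disc['p_fdr_adjusted']:.10g}",
            }
        )
    signals = pd.DataFrame(
        sig_rows,
        columns=["drug", "level", "outcome", "validated", "direction",
                 "hr_discovery", "p_fdr_discovery"],
    )
    signals_path = out_dir / "signals.csv"
    signals.to_csv(signals_path, index=False)
    written["signals"] = signals_path

    results_path = out_dir / "results.csv"
    write_results(res, results_path)
    written["results"] = results_path

    cfg = report.config.to_dict()
    cfg_json = json.dumps(cfg, sort_keys=True)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "split_seed": report.config.split_seed,
        "n_results": int(len(res)),
        "n_discovery_signals": len(report.discovery_signals),
        "n_validated_signals": len(report.validated_signals),
        "versions": _versions(),
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["manifest"] = manifest_path
    return written


def _versions() -> dict[str, str]:
    import matplotlib

    from . import __version__

    return {
        "mwascreen": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "matplotlib": matplotlib.__version__,
    }
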