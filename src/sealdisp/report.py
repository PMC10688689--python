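"""Publication-style outputs: count tables, posterior summaries, cohort plot.

Everything here is presentation: the numbers come from the ingest, detection
and sampling layers unchanged.  Tables are written as CSV (machine-readable,
exact) and Markdown (display, rates to 3 significant figures); the per-cohort
dispersal chart shows posterior means with 95% credible-interval bars for both
directions plus the overall hyper-mean.  A JSON run manifest captures input
digests, configuration and seeds so a run can be reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .ingest import CohortDispersalTable, ReappearanceTable
from .mcmc import PosteriorSummary


class MissingArtifactError(ValueError):
    """A required upstream result was not supplied."""


def _sig3(x: float) -> str:
    return f"{float(x):.3g}"


def render_tables(
    tallies: CohortDispersalTable,
    detection_summary: pd.DataFrame | None,
    dispersal_summary: dict[str, PosteriorSummary] | None,
    out_dir: str | Path,
    reappearance: ReappearanceTable | None = None,
) -> dict[str, Path]:
    """Write CSV and Markdown renditions of the study tables.

    ``detection_summary`` is the DataFrame from
    :meth:`~sealdisp.detection.DetectionPosterior.summary`;
    ``dispersal_summary`` maps origin colony to its fitted
    :class:`~sealdisp.mcmc.PosteriorSummary`.  Pass ``None`` only for stages
    that were genuinely not run; asking for a table whose inputs are missing
    raises :class:`MissingArtifactError`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if tallies is None:
        raise MissingArtifactError("cohort tallies are required")
    c1, c2 = tallies.colonies
    wide = tallies.counts.unstack("birth_colony")
    wide.columns = [f"{colony}_{kind}" for kind, colony in wide.columns]
    order = [
        f"{c}_{k}" for c in (c1, c2) for k in ("tagged", "breeding", "resident", "emigrant")
    ]
    wide = wide[order].fillna(0).astype(int)
    total = wide.sum()
    total.name = "Total"
    path = out_dir / "cohort_dispersal.csv"
    pd.concat([wide, total.to_frame().T]).rename_axis("birth_year").to_csv(path)
    written["cohort_dispersal"] = path
    md = out_dir / "cohort_dispersal.md"
    md.write_text(
        pd.concat([wide, total.to_frame().T]).to_markdown() + "\n", encoding="utf-8"
    )
    written["cohort_dispersal_md"] = md

    if reappearance is not None:
        path = out_dir / "reappearance.csv"
        reappearance.counts.assign(
            none=reappearance.counts["n_year1"]
            - reappearance.counts["same"]
            - reappearance.counts["other"]
        ).to_csv(path)
        written["reappearance"] = path

    if detection_summary is not None:
        path = out_dir / "detection_summary.csv"
        detection_summary.to_csv(path, index=False)
        written["detection"] = path
        md = out_dir / "detection_summary.md"
        show = detection_summary.copy()
        for col in ("mean", "ci_low", "ci_high"):
            show[col] = show[col].map(_sig3)
        md.write_text(show.to_markdown(index=False) + "\n", encoding="utf-8")
        written["detection_md"] = md

    if dispersal_summary is not None:
        if not dispersal_summary:
            raise MissingArtifactError("dispersal_summary supplied but empty")
        frames = []
        for origin, summ in dispersal_summary.items():
            t = summ.table.copy()
            t.insert(0, "origin", origin)
            frames.append(t.reset_index())
        path = out_dir / "dispersal_summary.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        written["dispersal"] = path
    return written


def parse_cohort_table(path: str | Path) -> CohortDispersalTable:
    """Read back a rendered cohort table; exact inverse of ``render_tables``."""
    wide = pd.read_csv(path, index_col="birth_year")
    wide = wide.drop(index="Total")
    wide.index = wide.index.astype(int)
    colonies = []
    for col in wide.columns:
        colony = col.rsplit("_", 1)[0]
        if colony not in colonies:
            colonies.append(colony)
    rows = []
    for year, row in wide.iterrows():
        for colony in colonies:
            rows.append(
                (
                    int(year),
                    colony,
                    int(row[f"{colony}_tagged"]),
                    int(row[f"{colony}_breeding"]),
                    int(row[f"{colony}_resident"]),
                    int(row[f"{colony}_emigrant"]),
                )
            )
    frame = pd.DataFrame(
        rows,
        columns=["birth_year", "birth_colony", "tagged", "breeding", "resident", "emigrant"],
    ).set_index(["birth_year", "birth_colony"])
    return CohortDispersalTable(counts=frame, colonies=tuple(colonies))


def plot_annual_dispersal(
    summaries: dict[str, PosteriorSummary], out_path: str | Path
) -> tuple[Path, pd.DataFrame]:
    """Point-and-interval chart of annual dispersal per cohort, by direction.

    Each direction contributes one triple (mean, 2.5%, 97.5%) per cohort plus
    one for the overall hyper-mean, drawn dashed at the right edge.  Returns
    the figure path and the plotted triples, so the data content (the
    contract) can be checked independently of styling.
    """
    if not summaries:
        raise MissingArtifactError("no dispersal summaries to plot")
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    colors = ["#c23b22", "#1f77b4", "#2ca02c"]
    triples = []
    for d, (origin, summ) in enumerate(summaries.items()):
        t = summ.table
        annual = t[t.index.str.startswith("mu_")]
        years = [int(name.split("_")[1]) for name in annual.index]
        offs = 0.15 * (d - (len(summaries) - 1) / 2)
        x = [y + offs for y in years]
        ax.errorbar(
            x,
            annual["mean"],
            yerr=[annual["mean"] - annual["ci_low"], annual["ci_high"] - annual["mean"]],
            fmt="o",
            color=colors[d % len(colors)],
            label=f"from {origin}",
            markersize=4,
            elinewidth=1,
        )
        for name, row in annual.iterrows():
            triples.append((origin, name, row["mean"], row["ci_low"], row["ci_high"]))
        if "theta" in t.index:
            row = t.loc["theta"]
            x_mean = max(years) + 1.5 + offs
            ax.errorbar(
                [x_mean],
                [row["mean"]],
                yerr=[[row["mean"] - row["ci_low"]], [row["ci_high"] - row["mean"]]],
                fmt="o",
                color=colors[d % len(colors)],
                linestyle="--",
                markersize=5,
            )
            triples.append((origin, "theta", row["mean"], row["ci_low"], row["ci_high"]))
    ax.set_xlabel("birth cohort")
    ax.set_ylabel("natal dispersal rate")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    data = pd.DataFrame(
        triples, columns=["origin", "parameter", "mean", "ci_low", "ci_high"]
    )
    return out_path, data


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: inputs, config, seeds, version."""

    input_digests: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    software_version: str = ""
    timestamp: str = ""

    @staticmethod
    def digest(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def add_input(self, path: str | Path) -> None:
        self.input_digests[Path(path).name] = self.digest(path)

    def finalize(self) -> "RunManifest":
        from . import __version__

        self.software_version = __version__
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S%z")
        return self

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return path
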