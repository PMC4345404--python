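"""Figure rendering for a pipeline report.

Every figure gets a TSV twin holding exactly the numbers plotted, so plots
can be regenerated (and checked) without rerunning the pipeline.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from . import peaks as peaks_mod  # noqa: E402
from .io_formats import write_tsv  # noqa: E402


def make_figures(report, outdir) -> list[Path]:
    """Render the report's figure set (mappability, taxonomy, overlap,
    annotation, TSS density, chromosomal distribution) with TSV twins.
    Returns the list of files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def save(fig, name, df):
        png = outdir / f"{name}.png"
        tsv = outdir / f"{name}.tsv"
        fig.savefig(png, dpi=110, bbox_inches="tight")
        plt.close(fig)
        write_tsv(df, tsv)
        written.extend([png, tsv])

    # mappability stacked bars
    rows = []
    for run, m in report.mappability.items():
        rows.append({"run": run, "unique": m["p_unique"],
                     "multi": m["p_multi"], "unaligned": m["p_unaligned"]})
    df = pd.DataFrame(rows)
    fig, ax = plt.subplots(figsize=(4, 3))
    bottom = pd.Series([0.0] * len(df))
    for cls, color in (("unique", "#4c72b0"), ("multi", "#dd8452"),
                       ("unaligned", "#c44e52")):
        ax.bar(df["run"], df[cls], bottom=bottom, label=cls, color=color)
        bottom = bottom + df[cls]
    ax.set_ylabel("proportion of reads")
    ax.set_title("Read mappability")
    ax.legend(fontsize=7)
    save(fig, "mappability", df)

    # taxonomy breakdown (kingdom rollup)
    df = pd.DataFrame(report.taxonomy_breakdown.get("kingdom", []))
    fig, ax = plt.subplots(figsize=(4, 3))
    if not df.empty:
        ax.bar(df["name"], df["fraction"], color="#55a868")
        ax.tick_params(axis="x", rotation=30)
    ax.set_ylabel("fraction of assigned reads")
    ax.set_title("Taxonomic origin of unaligned reads")
    save(fig, "taxonomy_breakdown", df if not df.empty else pd.DataFrame())

    # peak-set overlap
    ov = report.overlap
    df = pd.DataFrame([
        {"set": "ordinary only", "count": ov["n_a_only"]},
        {"set": "overlap", "count": ov["n_overlap_a"]},
        {"set": "recovered only", "count": ov["n_b_only"]},
    ])
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(df["set"], df["count"], color=["#4c72b0", "#937860", "#c44e52"])
    ax.set_ylabel("peaks")
    ax.set_title("Ordinary vs recovered peak overlap")
    save(fig, "peak_overlap", df)

    # annotation proportions
    rows = []
    for name, props in report.annotation.items():
        for cat, frac in props.items():
            rows.append({"set": name, "category": cat, "fraction": frac})
    df = pd.DataFrame(rows)
    fig, ax = plt.subplots(figsize=(6, 3))
    if not df.empty:
        piv = df.pivot(index="category", columns="set", values="fraction")
        piv = piv.reindex(list(peaks_mod.CATEGORIES))
        piv.plot.bar(ax=ax)
        ax.set_ylabel("fraction of peaks")
    ax.set_title("Peak genomic context")
    save(fig, "annotation", df)

    # TSS density of both peak sets
    from .peaks import tss_density  # local import to keep module load light

    save_df = []
    fig, ax = plt.subplots(figsize=(4, 3))
    genes = getattr(report, "_genes", None)
    for name, pset in (("ordinary", report.ordinary_peaks),
                       ("recovered", report.recovered_peaks)):
        if genes is None or not pset:
            continue
        curve = tss_density(pset, genes)
        if curve.empty:
            continue
        ax.plot(curve.grid, curve.density, label=name)
        d = curve.to_frame()
        d["set"] = name
        save_df.append(d)
    ax.set_xlabel("summit distance to nearest TSS (bp)")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    ax.set_title("Peak density around TSS")
    save(fig, "tss_density",
         pd.concat(save_df) if save_df else pd.DataFrame())

    # chromosomal distribution
    rows = []
    for name, recs in report.chrom_distribution.items():
        for r in recs:
            rows.append({"set": name, **{k: r[k] for k in
                                         ("chrom", "count", "proportion")}})
    df = pd.DataFrame(rows)
    fig, ax = plt.subplots(figsize=(5, 3))
    if not df.empty:
        piv = df.pivot(index="chrom", columns="set", values="proportion")
        piv.plot.bar(ax=ax)
        ax.set_ylabel("proportion of peaks")
    ax.set_title("Chromosomal distribution of peaks")
    save(fig, "chrom_distribution", df)

    return written
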