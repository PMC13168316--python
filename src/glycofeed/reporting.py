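"""Run manifests and assembled report tables.

Each pipeline stage writes its output files plus a single ``manifest.json``
recording the command, a hash of the effective configuration, the seed, and
the input/output paths, so a results directory is self-describing and a
rerun with identical inputs and seed overwrites with identical content.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .compositional import (
    ClrMatrix,
    clr_transform,
    dispersion_test,
    pca,
    permanova,
    spearman_sample_correlation,
)
from .differential import fit_cell_means, pairwise_cell_contrast
from .glycoforms import GlycationProfile, GlycoformTable, galactosylation_index, glycation_index
from .io import write_table
from .kinetics import CultureTimeCourse, rate_summary_table


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int | None
    inputs: list[str]
    outputs: list[str]
    timestamp: str = ""
    version: str = __version__

    def write(self, outdir: str | Path) -> Path:
        path = Path(outdir) / "manifest.json"
        data = asdict(self)
        if not data["timestamp"]:
            data["timestamp"] = datetime.now(timezone.utc).isoformat()
        path.write_text(json.dumps(data, indent=2) + "\n")
        return path


def config_hash(config: object) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    try:
        payload = json.dumps(config, sort_keys=True, default=str)
    except TypeError:
        payload = repr(config)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(
    outdir: str | Path, command: str, *, seed: int | None = None,
    config: object = None, inputs: list[str] | None = None,
    outputs: list[str] | None = None,
) -> Path:
    Path(outdir).mkdir(parents=True, exist_ok=True)
    return RunManifest(
        command=command, config_hash=config_hash(config), seed=seed,
        inputs=[str(p) for p in (inputs or [])],
        outputs=[str(p) for p in (outputs or [])],
    ).write(outdir)


def indices_table(
    glycoforms: GlycoformTable, glycation: GlycationProfile | None = None
) -> pd.DataFrame:
    """Per-sample galactosylation (and optionally glycation) indices, tidy."""
    out = glycoforms.metadata.copy()
    out["galactosylation_index"] = galactosylation_index(glycoforms)
    if glycation is not None:
        gi = glycation_index(glycation)
        out["glycation_index"] = gi.reindex(out.index)
    return out.reset_index(names="sample_id")


def multivariate_report(
    clr: ClrMatrix, outdir: str | Path, n_perm: int = 999, seed: int | None = None
) -> dict[str, Path]:
    """PERMANOVA (additive and interaction models), dispersion, PCA,
    sample correlations — written as CSVs into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    additive = permanova(clr, ["phase", "strategy"], n_perm=n_perm, seed=seed)
    inter = permanova(clr, ["phase", "strategy", "phase:strategy"],
                      n_perm=n_perm, seed=seed)
    for name, res in [("permanova_additive", additive),
                      ("permanova_interaction", inter)]:
        p = outdir / f"{name}.csv"
        write_table(res.table.reset_index(), p)
        written[name] = p

    for name, grouping in [("dispersion_phase", "phase"),
                           ("dispersion_strategy", "strategy")]:
        res = dispersion_test(clr, grouping, n_perm=n_perm, seed=seed)
        frame = res.group_means.rename("mean_dispersion").rename_axis("group").reset_index()
        frame["F"] = res.F
        frame["p"] = res.p
        p = outdir / f"{name}.csv"
        write_table(frame, p)
        written[name] = p

    pc = pca(clr)
    scores = pc.scores.copy()
    scores.insert(0, "sample_id", scores.index)
    p = outdir / "pca_scores.csv"
    write_table(scores, p)
    written["pca_scores"] = p
    p = outdir / "pca_loadings.csv"
    write_table(pc.loadings.reset_index(names="component"), p)
    written["pca_loadings"] = p
    p = outdir / "pca_explained.csv"
    write_table(pd.DataFrame({
        "component": [f"PC{i+1}" for i in range(len(pc.explained_variance_ratio))],
        "explained_variance_fraction": pc.explained_variance_ratio}), p)
    written["pca_explained"] = p

    corr = spearman_sample_correlation(clr)
    p = outdir / "sample_correlation.csv"
    write_table(corr.reset_index(names="sample_id"), p)
    written["sample_correlation"] = p
    return written


def differential_report(
    clr: ClrMatrix, outdir: str | Path, moderate: bool = True
) -> Path:
    """Standard contrast battery: stationary vs exponential within every
    strategy, and each Gal+ strategy vs its counterpart within each phase."""
    fit = fit_cell_means(clr)
    cells = set(fit.cells)
    frames = []
    strategies = sorted({c.split("|")[0] for c in cells})
    for s in strategies:
        a, b = f"{s}|sta", f"{s}|exp"
        if a in cells and b in cells:
            res = pairwise_cell_contrast(fit, a, b, moderate=moderate)
            frames.append(res.table.assign(comparison=res.comparison))
    for plus, base in [("STD+", "STD"), ("LoG+", "LoG"), ("HIP+", "HIP")]:
        for phase in ("exp", "sta"):
            a, b = f"{plus}|{phase}", f"{base}|{phase}"
            if a in cells and b in cells:
                res = pairwise_cell_contrast(fit, a, b, moderate=moderate)
                frames.append(res.table.assign(comparison=res.comparison))
    out = pd.concat(frames).reset_index()
    out = out[["comparison", "glycoform", "log2FC", "t", "p", "adj_p", "stars"]]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "contrasts.csv"
    write_table(out, path)
    return path


def rates_report(courses: list[CultureTimeCourse], outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = pd.concat([rate_summary_table(c) for c in courses], ignore_index=True)
    path = outdir / "rates.csv"
    write_table(table, path)
    return path
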