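"""End-to-end workflow: file I/O, z-score standardization, multi-gene
screening and the rank -> test -> plot pipeline.

Nutrient variables come in wildly different units (macronutrients in mg,
micronutrients in IU); since the LC similarity kernel has unit bandwidth,
the variable with the largest raw range would dominate every distance.  All
LC computations on real-unit data therefore z-score each nutrient column
first, which is the default throughout this module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import lc_test
from .search import LCOpt, enumerate_combinations

logger = logging.getLogger("lcn2g")

__all__ = [
    "load_and_align",
    "standardize",
    "zscore",
    "ScreenResult",
    "screen_genes",
    "run_pipeline",
]


def _read_table(path) -> pd.DataFrame:
    """Read a CSV/TSV matrix with a header row and the first column as index."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna() | c.isna()).all()]
    if len(bad):
        for col in bad:
            coerced = pd.to_numeric(df[col], errors="coerce")
            row = df.index[coerced.isna() & df[col].notna()][0]
            raise ValueError(
                f"non-numeric value in {path.name}, row {row!r}, column {col!r}"
            )
    return df.apply(pd.to_numeric, errors="coerce")


def load_and_align(nutrient_file, expression_file) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load nutrient and expression matrices and inner-join them on sample ID.

    The nutrient table is samples x nutrients.  The expression table may be
    genes x samples or samples x genes; orientation is auto-detected by which
    axis shares IDs with the nutrient table.  Samples with any missing
    nutrient value are dropped (logged).  Returns ``(nutrients, expression)``
    with expression as genes x samples, columns aligned to the nutrient rows.
    """
    X = _read_table(nutrient_file)
    E = _read_table(expression_file)
    x_ids = set(X.index.astype(str))
    X.index = X.index.astype(str)
    overlap_cols = len(x_ids & set(E.columns.astype(str)))
    overlap_rows = len(x_ids & set(E.index.astype(str)))
    if overlap_rows > overlap_cols:
        E = E.T  # supplied samples x genes
    E.columns = E.columns.astype(str)
    shared = [s for s in X.index if s in set(E.columns)]
    if not shared:
        raise ValueError("no overlapping sample IDs between nutrient and expression files")
    dropped_unshared = len(X.index) - len(shared)
    X = X.loc[shared]
    E = E[shared]
    missing = X.isna().any(axis=1) | E.isna().any(axis=0).values
    n_missing = int(missing.sum())
    if n_missing:
        keep = ~missing.values
        X = X.loc[keep]
        E = E.loc[:, keep]
    if dropped_unshared or n_missing:
        logger.warning(
            "alignment dropped %d unshared and %d incomplete samples; %d remain",
            dropped_unshared, n_missing, X.shape[0],
        )
    return X, E


def zscore(values: np.ndarray) -> np.ndarray:
    """Column-wise z-score with sample SD (ddof=1); raises on constant columns."""
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance column(s) at index {bad.tolist()}")
    return (values - values.mean(axis=0)) / sd


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """z-score every nutrient column (mean 0, sample SD 1).

    Raises a ValueError naming the column if any column is constant.
    """
    sd = X.std(axis=0, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"zero-variance column(s): {constant}")
    return (X - X.mean(axis=0)) / sd


@dataclass
class ScreenResult:
    """Per-gene screening outcome over all C(p, k) combinations."""

    table: pd.DataFrame  # gene, min_p, best_combination, kept, note
    alpha: float
    k: int
    n_combinations: int

    @property
    def kept_genes(self) -> list[str]:
        return self.table.loc[self.table["kept"], "gene"].tolist()


def screen_genes(
    X: pd.DataFrame,
    E: pd.DataFrame,
    k: int = 2,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ScreenResult:
    """LC-Test every gene against every k-combination of nutrient variables.

    A gene is kept when its smallest permutation p-value over combinations is
    <= alpha (no multiplicity correction, so pure-noise genes are kept at a
    family-wise inflated rate ~ 1 - (1 - alpha)^C(p,k)).  Constant genes are
    dropped as degenerate rather than aborting the screen.
    """
    Xz = standardize(X)
    combos = enumerate_combinations(X.shape[1], k)
    rng = np.random.default_rng(seed)
    rows = []
    for gene in E.index:
        G = E.loc[gene].to_numpy(dtype=float)
        if np.ptp(G) == 0:
            rows.append((gene, np.nan, None, False, "dropped: degenerate"))
            continue
        best_p, best_combo = np.inf, None
        for combo in combos:
            res = lc_test(Xz.values, combo, G, B=B, rng=rng)
            if res.p_value < best_p:
                best_p, best_combo = res.p_value, combo
        names = tuple(X.columns[list(best_combo)])
        rows.append((gene, best_p, names, best_p <= alpha, ""))
    table = pd.DataFrame(rows, columns=["gene", "min_p", "best_combination", "kept", "note"])
    return ScreenResult(table=table, alpha=alpha, k=k, n_combinations=len(combos))


def run_pipeline(
    nutrient_file,
    expression_file,
    genes: list[str],
    out_dir,
    k: int = 2,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    top: int = 20,
    include: list[str] | None = None,
    exclude: list[str] | None = None,
    plot: bool = True,
) -> Path:
    """Full workflow for a list of genes: rank combinations by LC, test the
    top combination, and draw its response surface when significant.

    ``include``/``exclude`` restrict the nutrient variables considered (the
    user's redundancy filtering).  Writes, per gene, a ranked-combination TSV
    and (when the top combination is significant) a surface PNG, plus a JSON
    run log with all parameters.  Returns the output directory.
    """
    from . import __version__
    from .ngf import fit_ngf_surface, render_ngf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X, E = load_and_align(nutrient_file, expression_file)
    if include:
        X = X[list(include)]
    if exclude:
        X = X.drop(columns=list(exclude))
    Xz = standardize(X)
    log: dict = {
        "version": __version__,
        "parameters": dict(k=k, B=B, alpha=alpha, seed=seed, top=top,
                           nutrients=list(X.columns), n_samples=int(X.shape[0])),
        "genes": {},
    }
    rng = np.random.default_rng(seed)
    for gene in genes:
        entry: dict = {}
        try:
            G = E.loc[gene].to_numpy(dtype=float)
            est = LCOpt(k=k).fit(Xz.values, G)
            records = []
            for res in est.results_[:top]:
                names = [X.columns[c] for c in res.combination]
                records.append(names + [res.lc_value, res.rank])
            cols = [f"variable_{i + 1}" for i in range(k)] + ["lc_stat", "rank"]
            ranked = pd.DataFrame(records, columns=cols)
            best = est.results_[0]
            test = lc_test(Xz.values, best.combination, G, B=B, rng=rng)
            ranked.loc[0, "p_value"] = test.p_value
            tsv = out_dir / f"{gene}_ranked.tsv"
            ranked.to_csv(tsv, sep="\t", index=False)
            entry.update(
                top_combination=[X.columns[c] for c in best.combination],
                lc_stat=best.lc_value, p_value=test.p_value,
                significant=bool(test.p_value <= alpha), ranked_table=tsv.name,
            )
            if entry["significant"] and plot and k == 2:
                a, b = best.combination
                surf = fit_ngf_surface(X.values[:, [a, b]], G)
                png = out_dir / f"{gene}_surface.png"
                render_ngf(surf, out_path=png, title=gene,
                           xlabel=X.columns[a], ylabel=X.columns[b])
                entry["plot"] = png.name
        except Exception as exc:  # keep partial outputs, record the failure
            entry["error"] = f"{type(exc).__name__}: {exc}"
            logger.error("pipeline failed for gene %s: %s", gene, exc)
        log["genes"][gene] = entry
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out_dir
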