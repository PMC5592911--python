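"""Dataset-level runner: parse count/phenotype tables, test every gene, adjust.

Input is a TCGA-style isoform expression table — TSV with ``gene_id`` and
``isoform_id`` columns followed by one column per sample — plus a two-column
phenotype table mapping sample_id to a binary condition.  Output is one row
per gene with the score statistic, both p-values and BH q-values, written as
TSV alongside a JSON run-metadata sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import __version__
from .model_core import DegenerateGeneError, DesignVector, IsoformCountMatrix
from .vct_test import TestConfig, test_gene

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_SKIPPED = "skipped_degenerate"
STATUS_FELL_BACK = "fell_back_poisson"

RESULT_COLUMNS = ["gene_id", "p_isoforms_used", "family_used", "U", "chi2",
                  "p_theoretical", "p_empirical", "q_value", "status"]


def read_isoform_counts(path) -> list[IsoformCountMatrix]:
    """Read a wide isoform count TSV into per-gene count matrices.

    Requires ``gene_id`` and ``isoform_id`` columns; every remaining column is
    a sample.  Fractional values (RSEM-style expected counts) are rounded
    half-to-even with a logged message; negative or missing values are errors.
    Genes keep their file order, as do isoforms within a gene.
    """
    frame = pd.read_csv(path, sep="\t")
    for required in ("gene_id", "isoform_id"):
        if required not in frame.columns:
            raise ValueError(f"{path}: missing required column {required!r}")
    sample_cols = [c for c in frame.columns if c not in ("gene_id", "isoform_id")]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    dup = frame.duplicated(subset=["gene_id", "isoform_id"])
    if dup.any():
        pair = frame.loc[dup.idxmax(), ["gene_id", "isoform_id"]].tolist()
        raise ValueError(f"{path}: duplicate (gene, isoform) pair {tuple(pair)}")

    values = frame[sample_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        row, col = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(f"{path}: missing count at row {row + 2}, "
                         f"column {sample_cols[col]!r} (ragged sample set)")
    if (values < 0).any():
        row, col = map(int, np.argwhere(values < 0)[0])
        raise ValueError(f"{path}: negative count at row {row + 2}, "
                         f"column {sample_cols[col]!r}")
    rounded = np.round(values)          # numpy rounds half to even
    n_fractional = int(np.sum(rounded != values))
    if n_fractional:
        logger.info("%s: rounded %d fractional count value(s) half-to-even",
                    path, n_fractional)

    matrices = []
    # groupby(sort=False) preserves first-appearance gene order
    for gene_id, sub in frame.assign(**{
            c: rounded[:, k] for k, c in enumerate(sample_cols)}).groupby(
                "gene_id", sort=False):
        matrices.append(IsoformCountMatrix(
            counts=sub[sample_cols].to_numpy().T,   # samples x isoforms
            sample_ids=tuple(sample_cols),
            isoform_ids=tuple(sub["isoform_id"].astype(str)),
            gene_id=str(gene_id),
        ))
    return matrices


def read_phenotype(path, sample_ids) -> DesignVector:
    """Read a sample_id/condition TSV and align it to ``sample_ids``.

    Two-level conditions are mapped to {0, 1} by lexicographic order (logged);
    numeric 0/1 conditions pass through unchanged.
    """
    pheno = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for required in ("sample_id", "condition"):
        if required not in pheno.columns:
            raise ValueError(f"{path}: missing required column {required!r}")
    mapping = dict(zip(pheno["sample_id"], pheno["condition"]))
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"{path}: no phenotype for sample(s) {missing}")
    raw = [mapping[s] for s in sample_ids]
    levels = sorted(set(raw))
    if len(levels) == 1:
        raise ValueError(f"{path}: condition has a single level {levels[0]!r}")
    if set(str(v) for v in levels) <= {"0", "1"} or (
            all(isinstance(v, (int, float, np.number)) for v in levels)
            and set(float(v) for v in levels) <= {0.0, 1.0}):
        x = np.array([float(v) for v in raw])
    else:
        if len(levels) != 2:
            raise ValueError(f"{path}: condition must have exactly two levels, "
                             f"got {levels}")
        code = {levels[0]: 0.0, levels[1]: 1.0}
        logger.info("%s: condition coding %r -> 0, %r -> 1", path,
                    levels[0], levels[1])
        x = np.array([code[v] for v in raw])
    return DesignVector(x)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class RunConfig:
    """Dataset-run options (family/B/seed forwarded to the per-gene test)."""

    family: str = "auto"
    B: int = 5000
    seed: int = 0
    alpha: float = 0.05
    adjust: str = "bh"          # "bh" or "none"
    phi_threshold: float = 1e-3


def run_dataset(counts_path, pheno_path, config: RunConfig = RunConfig(),
                out_path=None) -> pd.DataFrame:
    """Test every gene in a dataset; one result row per input gene.

    q-values are computed over p_empirical when permutations are on, else over
    p_theoretical; degenerate genes are reported as skipped rows, never
    dropped silently.  Deterministic given ``config.seed``.
    """
    genes = read_isoform_counts(counts_path)
    if not genes:
        raise ValueError(f"{counts_path}: no genes found")
    x = read_phenotype(pheno_path, genes[0].sample_ids)

    rows = []
    n_fallback = n_skipped = 0
    for idx, gene in enumerate(genes):
        gene_seed = int(np.random.SeedSequence(
            entropy=config.seed, spawn_key=(idx,)).generate_state(1)[0] % (2**31))
        try:
            res = test_gene(gene, x, TestConfig(
                family=config.family, B=config.B, seed=gene_seed,
                phi_threshold=config.phi_threshold))
        except DegenerateGeneError:
            n_skipped += 1
            rows.append({"gene_id": gene.gene_id, "p_isoforms_used": 0,
                         "family_used": None, "U": np.nan, "chi2": np.nan,
                         "p_theoretical": np.nan, "p_empirical": np.nan,
                         "status": STATUS_SKIPPED})
            continue
        status = STATUS_OK
        if config.family == "auto" and res.fell_back_poisson:
            status = STATUS_FELL_BACK
            n_fallback += 1
        rows.append({"gene_id": gene.gene_id,
                     "p_isoforms_used": res.n_isoforms_used,
                     "family_used": res.family_used, "U": res.U,
                     "chi2": res.chi2, "p_theoretical": res.p_theoretical,
                     "p_empirical": res.p_empirical, "status": status})

    table = pd.DataFrame(rows)
    p_col = "p_empirical" if config.B > 0 else "p_theoretical"
    table["q_value"] = np.nan
    tested = table["status"] != STATUS_SKIPPED
    if config.adjust == "bh" and tested.any():
        table.loc[tested, "q_value"] = bh_adjust(table.loc[tested, p_col])
    elif config.adjust == "none":
        table.loc[tested, "q_value"] = table.loc[tested, p_col]
    table = table[RESULT_COLUMNS]

    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
        sidecar = {
            "config": asdict(config), "version": __version__,
            "n_genes": len(genes), "n_skipped_degenerate": n_skipped,
            "n_fell_back_poisson": n_fallback,
            "p_value_used_for_adjustment": p_col,
        }
        with open(f"{out_path}.meta.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
    return table
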