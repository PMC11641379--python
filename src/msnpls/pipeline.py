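"""End-to-end synthetic analysis: simulate, contrast, associate, enrich.

``run_all`` wires every stage together on generated data: cohort and feature
tables -> regional MS -> covariate-adjusted group contrast -> planted
expression matrix -> one-component PLS with permutation and bootstrap
inference -> gene-set overrepresentation.  Signal genes are planted against
the *observed* contrast t-map, so the transcriptomic signal tracks the group
effect exactly as measured, which is what the gene-recovery checks assume.

Every output file is written with fixed float formatting and sorted keys, so
two runs with the same seed are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import msn
from .cohort import write_covariate_table
from .contrast import GroupContrast, RegionalContrast
from .enrichment import GeneSetCollection, enrichment_table, write_background, write_gmt
from .expression import write_expression_matrix
from .pls import PLSAssociation
from .simulate import (
    SimulationParams,
    simulate_cohort,
    simulate_expression_matrix,
    simulate_gene_sets,
)


@dataclass
class PipelineResult:
    contrast: RegionalContrast
    pls: PLSAssociation
    expression: pd.DataFrame
    signal_genes: pd.DataFrame
    gene_sets: GeneSetCollection
    enrichment: pd.DataFrame
    regional_ms: pd.DataFrame


def run_all(
    params: SimulationParams,
    out_dir: str | Path | None = None,
    n_perm: int = 10_000,
    n_boot: int = 1_000,
) -> PipelineResult:
    """Run the full synthetic pipeline; optionally write all artefacts."""
    root = np.random.SeedSequence(params.seed)
    s_cohort, s_expr, s_sets, s_pls = root.spawn(4)

    records, tables = simulate_cohort(params, rng=np.random.default_rng(s_cohort))
    ms_table = msn.MorphometricSimilarity(params.regions).fit(tables).transform(tables)
    gc = GroupContrast().fit(ms_table, records)

    expression, signal_genes = simulate_expression_matrix(
        params, planted_pattern=gc.t_, rng=np.random.default_rng(s_expr)
    )
    pls = PLSAssociation(
        n_perm=n_perm, n_boot=n_boot, random_state=s_pls.generate_state(1)[0] % (2**31)
    ).fit(expression, gc.t_)

    collection = simulate_gene_sets(
        signal_genes,
        background=list(expression.columns),
        params=params,
        rng=np.random.default_rng(s_sets),
    )
    enr = enrichment_table(
        {"PLS_PLUS": pls.pls_plus_, "PLS_MINUS": pls.pls_minus_}, collection
    )

    result = PipelineResult(
        contrast=gc.result_,
        pls=pls,
        expression=expression,
        signal_genes=signal_genes,
        gene_sets=collection,
        enrichment=enr,
        regional_ms=ms_table,
    )
    if out_dir is not None:
        _write_outputs(result, records, tables, Path(out_dir), params)
    return result


def _write_outputs(result, records, tables, out_dir: Path, params: SimulationParams) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_covariate_table(records, out_dir / "covariates.tsv")
    msn.write_feature_tables(tables, out_dir / "features.tsv")
    msn.write_regional_ms(result.regional_ms, out_dir / "regional_ms.tsv")
    result.contrast.write(out_dir / "contrast.tsv")
    write_expression_matrix(result.expression, out_dir / "expression.tsv")
    result.signal_genes.to_csv(out_dir / "signal_genes.tsv", sep="\t", index=False)

    pls = result.pls
    summary = pd.DataFrame(
        [
            {
                "r": pls.r_,
                "r2": pls.r2_,
                "perm_p": pls.permutation_p_,
                "n_perm": pls.n_perm,
                "n_boot": pls.n_boot,
                "seed": params.seed,
                "n_pls_plus": len(pls.pls_plus_),
                "n_pls_minus": len(pls.pls_minus_),
            }
        ]
    )
    summary.to_csv(out_dir / "pls_summary.tsv", sep="\t", index=False, float_format="%.12g")
    pls.gene_scores_.to_csv(
        out_dir / "gene_scores.tsv", sep="\t", index=False, float_format="%.12g"
    )
    for name, genes in (("pls_plus.txt", pls.pls_plus_), ("pls_minus.txt", pls.pls_minus_)):
        with open(out_dir / name, "wt", encoding="utf-8") as fh:
            for gene in genes:
                fh.write(f"{gene}\n")
    write_gmt(result.gene_sets.sets, out_dir / "gene_sets.gmt")
    write_background(result.gene_sets.background, out_dir / "background.txt")
    result.enrichment.to_csv(
        out_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.12g"
    )
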