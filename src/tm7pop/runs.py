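"""Top-level analysis compositions behind the CLI commands.

Each run writes plain TSV/JSON outputs plus the serialized configuration
into its output directory, and is idempotent given (config, inputs).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .config import RunConfig
from .mining import (
    GenomeAssembly,
    QueryPanel,
    mine_genome,
    summarize_repertoire,
)
from .mining.pipeline import (
    write_gff3,
    write_candidate_fastas,
    write_summary_tsv,
    load_reference_panel,
)
from .mining.search import read_blast_tabular
from . import phylo
from .popgen import (
    PopulationAlignment,
    neutrality_tests,
    hudson_fst,
    snn_test,
    fdr_adjust,
)
from .snps import call_snps, per_snp_differentiation, fisher_exact_2x2

logger = logging.getLogger("tm7pop")


def _prepare_out(config: RunConfig, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    return out


# ---------------------------------------------------------------------------
# Mining


def run_mining(
    config: RunConfig,
    genome_fa: str | Path,
    queries_fa: str | Path | None,
    out_dir: str | Path,
    species: str = "species",
    hits_tsv: str | Path | None = None,
) -> dict:
    out = _prepare_out(config, out_dir)
    genome = GenomeAssembly.from_fasta(genome_fa)
    reference = load_reference_panel()
    if queries_fa is not None:
        queries = QueryPanel.from_fasta(queries_fa)
    else:
        from .mining.pipeline import query_panel_from_reference

        queries = query_panel_from_reference(reference)
    hits = read_blast_tabular(hits_tsv, genome) if hits_tsv else None

    candidates, log = mine_genome(
        genome,
        queries,
        reference=reference,
        hits=hits,
        evalue_cutoff=config.evalue_cutoff,
        min_hit_nt=config.min_hit_nt,
        merge_dist=config.merge_dist,
        window_nt=config.extension_window_nt,
        gap_min_n=config.gap_min_n,
        min_codons=config.min_codons,
        require_tm=config.require_tm,
    )
    logger.info("mining stages: %s", log)
    write_gff3(candidates, out / "candidates.gff3")
    write_candidate_fastas(candidates, out / "candidates_cds.fa", out / "candidates_protein.fa")
    summary = summarize_repertoire({species: candidates})
    write_summary_tsv(summary, out / "summary.tsv")
    (out / "stage_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return {"candidates": candidates, "summary": summary, "log": log}


# ---------------------------------------------------------------------------
# Independent contrasts


def run_pic(
    config: RunConfig,
    tree_path: str | Path,
    traits_path: str | Path,
    out_dir: str | Path,
    node_ages_path: str | Path | None = None,
) -> dict:
    out = _prepare_out(config, out_dir)
    if node_ages_path is not None:
        tree = phylo.tree_from_node_ages(tree_path, phylo.read_node_age_table(node_ages_path))
    else:
        tree = phylo.read_tree(tree_path)
    traits = phylo.read_trait_table(traits_path)

    results = {}
    tables = []
    for which in ("intact", "functional"):
        corr, pairs = phylo.lifestyle_correlation(tree, traits, which)
        results[which] = {"rho": corr.rho, "p_two_tailed": corr.p_two_tailed, "n": corr.n}
        pairs.to_csv(out / f"contrasts_{which}.tsv", sep="\t", index=False)
        tables.append(pairs)
    (out / "correlations.json").write_text(json.dumps(results, indent=2) + "\n")
    return {"results": results, "tables": tables}


# ---------------------------------------------------------------------------
# Population genetics


def _locus_files(directory: str | Path) -> list[Path]:
    exts = {".fa", ".fasta", ".fna"}
    return sorted(p for p in Path(directory).iterdir() if p.suffix in exts)


def _consensus_cds(aln: PopulationAlignment) -> str:
    """Majority base per column (ties alphabetical); used as the reference
    frame for SNP effect annotation."""
    out = []
    for j in range(aln.length):
        col = [s[j] for s in aln.seqs if s[j] in "ACGT"]
        if not col:
            out.append("N")
            continue
        tallies = {b: col.count(b) for b in set(col)}
        out.append(sorted(tallies, key=lambda b: (-tallies[b], b))[0])
    return "".join(out)


def diversity_table(
    loci: list[PopulationAlignment], config: RunConfig
) -> pd.DataFrame:
    """Per-locus, per-population diversity and neutrality statistics."""
    rows = []
    for k, aln in enumerate(loci):
        for pop in aln.population_labels():
            sub = aln.subset(pop)
            res = neutrality_tests(
                sub, reps=config.coalescent_reps, seed=config.seed + 1000 * k
            )
            rows.append(
                {
                    "locus": aln.locus,
                    "population": pop,
                    "n": res.n,
                    "S": res.s,
                    "pi": res.pi,
                    "theta_w": res.theta_w,
                    "tajima_d": res.tajima_d,
                    "p_tajima": res.p_tajima,
                    "fu_li_dstar": res.fu_li_dstar,
                    "p_fuli": res.p_fuli,
                }
            )
    return pd.DataFrame(rows)


def differentiation_table(
    loci: list[PopulationAlignment], config: RunConfig
) -> pd.DataFrame:
    """Per-locus FST, Snn and permutation p, FDR-adjusted across loci."""
    rows = []
    for k, aln in enumerate(loci):
        fst = hudson_fst(aln)
        snn, p = snn_test(aln, reps=config.permutation_reps, seed=config.seed + 77 * k)
        rows.append(
            {
                "locus": aln.locus,
                "fst": fst.fst if fst.defined else np.nan,
                "fst_defined": fst.defined,
                "snn": snn,
                "p_snn": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_fdr"] = fdr_adjust(df["p_snn"].tolist())
    df["significant"] = df["p_fdr"] < config.fdr_alpha
    return df


def run_popgen(
    config: RunConfig,
    loci_dir: str | Path,
    out_dir: str | Path,
    noncoding_dir: str | Path | None = None,
    population_map: dict[str, str] | None = None,
) -> dict:
    out = _prepare_out(config, out_dir)
    loci = [
        PopulationAlignment.from_fasta(p, population_map=population_map)
        for p in _locus_files(loci_dir)
    ]
    if not loci:
        raise ValueError(f"no FASTA loci found in {loci_dir}")

    div = diversity_table(loci, config)
    div.to_csv(out / "diversity_coding.tsv", sep="\t", index=False)
    diff = differentiation_table(loci, config)
    diff.to_csv(out / "differentiation.tsv", sep="\t", index=False)

    # per-SNP analysis on coding loci
    all_snps = []
    cds_by_locus = {}
    for aln in loci:
        try:
            snps = call_snps(aln)
        except ValueError:
            logger.warning("locus %s not in frame; per-SNP analysis skipped", aln.locus)
            continue
        cds_by_locus[aln.locus] = _consensus_cds(aln)
        all_snps.extend(snps)
    all_snps, sig_counts = per_snp_differentiation(
        all_snps, cds_by_locus, alpha=config.fdr_alpha, family=config.fdr_family
    )
    snp_rows = [
        {
            "locus": s.locus,
            "column": s.column,
            "codon": s.codon_index,
            "effect": s.effect,
            "ref": s.ref,
            "alt": s.alt,
            "table": str(s.table),
            "p_fisher": s.p_fisher,
            "p_fdr": s.p_fdr,
        }
        for s in all_snps
    ]
    pd.DataFrame(snp_rows).to_csv(out / "snps.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"locus": k, "significant_nonsyn_snps": v} for k, v in sorted(sig_counts.items())]
    ).to_csv(out / "snp_locus_counts.tsv", sep="\t", index=False)

    report: dict = {
        "n_loci": len(loci),
        "significant_loci_snn": int(diff["significant"].sum()),
        "loci_with_significant_nonsyn_snp": sum(1 for v in sig_counts.values() if v > 0),
    }

    # paired t-test of per-locus pi between the two populations
    pops = loci[0].population_labels()
    if len(pops) == 2:
        wide = div.pivot(index="locus", columns="population", values="pi")
        t_res = _scipy_stats.ttest_rel(wide[pops[0]], wide[pops[1]])
        report["paired_t_pi"] = {
            "pop_order": pops,
            "t": float(t_res.statistic),
            "p_two_tailed": float(t_res.pvalue),
        }

    if noncoding_dir is not None:
        nc_loci = [
            PopulationAlignment.from_fasta(p, population_map=population_map)
            for p in _locus_files(noncoding_dir)
        ]
        nc_div = diversity_table(nc_loci, config)
        nc_div.to_csv(out / "diversity_noncoding.tsv", sep="\t", index=False)
        nc_diff = differentiation_table(nc_loci, config)
        nc_diff.to_csv(out / "differentiation_noncoding.tsv", sep="\t", index=False)

        a = int(diff["significant"].sum())
        b = len(diff) - a
        c = int(nc_diff["significant"].sum())
        d = len(nc_diff) - c
        report["fisher_differentiated_fraction"] = {
            "table": [[a, b], [c, d]],
            "p_two_tailed": fisher_exact_2x2(((a, b), (c, d))),
        }
        # Mann-Whitney U of per-locus pi, coding vs noncoding, per population
        report["mannwhitney_pi"] = {}
        for pop in pops:
            x = div[div["population"] == pop]["pi"]
            y = nc_div[nc_div["population"] == pop]["pi"]
            mw = _scipy_stats.mannwhitneyu(x, y, alternative="two-sided")
            report["mannwhitney_pi"][pop] = {
                "U": float(mw.statistic),
                "p_two_tailed": float(mw.pvalue),
            }

    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return {"diversity": div, "differentiation": diff, "report": report}
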