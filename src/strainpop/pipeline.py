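"""End-to-end pipeline driver: simulate or load inputs, run every analysis.

The pipeline consumes either a simulated community or externally produced
inputs (counts TSV, strain haplotypes TSV, strain tree, per-sample strain
frequencies) and emits, per run: a per-sample π table, the pairwise F_ST
matrix, per-gene and genome-wide pN/pS, the Neutrality Index at strain and
clade level, per-sample allele-frequency spectra, strain presence/dominance
calls, α- and β-diversity tables, association tests, and a machine-readable
run manifest.  All randomness flows from one seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diversity, popgen, simdata, snv, strains
from .io import read_frequencies_tsv, write_fasta, write_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "strainpop_out"
    seed: int = 0
    # input paths; when counts is None the bundled simulator provides inputs
    counts: str | None = None
    haplotypes: str | None = None
    tree: str | None = None
    frequencies: str | None = None
    genes_fasta: str | None = None
    # simulator overrides (used only in simulate mode)
    n_strains: int = 11
    clade_sizes: tuple | None = None
    genome_length: int = 30000
    n_genes: int = 50
    n_samples: int = 19
    coverage: float = 100.0
    seq_error: float = 0.001
    dirichlet_alpha: float = 0.3
    invariant_snv_rate: float = 5e-4
    d_between: float = 150.0
    d_within: float = 16.0
    # analysis thresholds
    poly_lo: float = 0.05
    poly_hi: float = 0.95
    present_min: float = 0.05
    dominant_min: float = 0.90
    major_min: float = 0.90
    afs_bins: int = 20
    n_perm: int = 999

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key=value configuration file; '#' comments allowed."""
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise KeyError(f"unknown configuration key {key!r}")
            ftype = fields[key].type
            if key == "clade_sizes":
                kwargs[key] = tuple(int(x) for x in val.split(",")) if val else None
            elif "int" in str(ftype):
                kwargs[key] = int(val)
            elif "float" in str(ftype):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of result objects and writes files."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # -- inputs ------------------------------------------------------------
    if config.counts is None:
        sim_cfg = simdata.SimulationConfig(
            n_strains=config.n_strains,
            clade_sizes=config.clade_sizes,
            d_between=config.d_between,
            d_within=config.d_within,
            genome_length=config.genome_length,
            n_genes=config.n_genes,
            n_samples=config.n_samples,
            coverage=config.coverage,
            seq_error=config.seq_error,
            dirichlet_alpha=config.dirichlet_alpha,
            invariant_snv_rate=config.invariant_snv_rate,
            seed=seed,
        )
        truth = simdata.simulate_strains(sim_cfg)
        counts = simdata.simulate_counts(truth, sim_cfg)
        haplotypes = truth.to_haplotype_set()
        tree = truth.tree_newick
        frequencies = truth.frequencies
        genes = popgen.CodingGeneSet(truth.coding_genes())
        ref_alleles = {
            truth.pos_to_site(int(p)): truth.root_seq[int(p)]
            for p in counts_positions(truth)
        }
        truth.write(outdir / "inputs")
        counts.to_tsv(outdir / "inputs" / "counts.tsv", header_comment=f"simulated, seed={seed}")
        write_fasta(genes.genes, outdir / "inputs" / "genes.fasta")
    else:
        counts = snv.AlleleCountMatrix.from_tsv(config.counts)
        haplotypes = (
            strains.StrainHaplotypeSet.from_tsv(config.haplotypes) if config.haplotypes else None
        )
        tree = Path(config.tree).read_text().strip() if config.tree else None
        frequencies = read_frequencies_tsv(config.frequencies) if config.frequencies else None
        genes = None
        if config.genes_fasta:
            from Bio import SeqIO

            genes = popgen.CodingGeneSet(
                {r.id: str(r.seq).upper() for r in SeqIO.parse(config.genes_fasta, "fasta")}
            )
        ref_alleles = None
        if haplotypes is not None:
            haplotypes.tree_newick = haplotypes.tree_newick or tree

    samples = counts.samples
    if frequencies is not None:
        mismatch = sorted(set(samples) ^ set(frequencies.index))
        if mismatch:
            raise ValueError(f"sample ids differ between counts and frequencies: {mismatch}")

    results: dict = {}

    # -- SNVs --------------------------------------------------------------
    records = snv.call_snvs(counts, ref_alleles=ref_alleles)
    bial = snv.biallelic(records)
    snv_rows = []
    for rec in records:
        for s in samples:
            f = rec.freqs.get(s, float("nan"))
            if np.isnan(f):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cls = snv.classify_polymorphic(rec, s, config.poly_lo, config.poly_hi)
            snv_rows.append(
                {"gene_id": rec.gene_id, "pos": rec.pos, "sample": s,
                 "alt_freq": round(f, 6), "class": cls.value if cls else "undefined"}
            )
    snv_table = pd.DataFrame(snv_rows, columns=["gene_id", "pos", "sample", "alt_freq", "class"])
    write_table(snv_table, outdir / "snv_classes.tsv", "snv_classification",
                {"lo": config.poly_lo, "hi": config.poly_hi, "seed": seed})
    results["snvs"] = records

    # -- π and F_ST --------------------------------------------------------
    pi_rows = []
    for s in samples:
        r = popgen.pi_intra(counts, s)
        pi_rows.append({"sample": s, "pi": r.value, "n_sites_used": r.n_sites_used})
    pi_table = pd.DataFrame(pi_rows).set_index("sample")
    write_table(pi_table, outdir / "pi_intra.tsv", "pi_intra",
                {"genome_length": counts.genome_length, "seed": seed}, index_label="sample")
    results["pi"] = pi_table

    if len(samples) > 1:
        fst_m = popgen.fst_matrix(counts)
    else:
        warnings.warn("single sample: F_ST matrix empty", stacklevel=2)
        fst_m = pd.DataFrame(index=samples[:0], columns=samples[:0], dtype=float)
    write_table(fst_m, outdir / "fst_matrix.tsv", "fst",
                {"genome_length": counts.genome_length, "seed": seed}, index_label="sample")
    results["fst"] = fst_m

    # -- pN/pS and NI ------------------------------------------------------
    if genes is not None:
        by_gene: dict = {}
        for rec in bial:
            by_gene.setdefault(rec.gene_id, []).append(rec)
        pnps_rows = []
        for gid, seq in genes.genes.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val = popgen.pnps_gene(by_gene.get(gid, ()), seq, table_id=genes.table_id)
            obs_n, obs_s = popgen.observed_ns(by_gene.get(gid, ()), seq, genes.table_id)
            pnps_rows.append({"gene_id": gid, "obs_n": obs_n, "obs_s": obs_s, "pnps": val})
        pnps_table = pd.DataFrame(pnps_rows).set_index("gene_id")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gw = popgen.pnps_genome(by_gene, genes)
        write_table(pnps_table, outdir / "pnps_per_gene.tsv", "pnps",
                    {"pseudocount_s": 1, "genome_wide": round(gw, 6) if not np.isnan(gw) else "nan",
                     "seed": seed}, index_label="gene_id")
        results["pnps_per_gene"] = pnps_table
        results["pnps_genome"] = gw

        ni_rows = []
        if haplotypes is not None:
            for level in ("strain", "clade"):
                try:
                    ni = popgen.ni_from_snvs(bial, haplotypes, genes, level=level)
                    ni_rows.append({"level": level, "NI": ni.value, "pnps": ni.pnps,
                                    "dnds": ni.dnds, "dN": ni.counts.dN, "dS": ni.counts.dS,
                                    "pN": ni.counts.pN, "pS": ni.counts.pS})
                except ValueError as err:
                    ni_rows.append({"level": level, "NI": float("nan"), "note": str(err)})
            ni_table = pd.DataFrame(ni_rows)
            write_table(ni_table, outdir / "neutrality_index.tsv", "neutrality_index",
                        {"seed": seed})
            results["ni"] = ni_table

    # -- strains: presence, dominance, AFS ---------------------------------
    if frequencies is not None:
        pres = strains.strain_presence_and_dominance(
            frequencies, config.present_min, config.dominant_min
        )
        pres_out = pres.copy()
        pres_out["present"] = pres_out["present"].map(lambda v: ",".join(v))
        write_table(pres_out, outdir / "strain_presence.tsv", "presence_dominance",
                    {"present_min": config.present_min, "dominant_min": config.dominant_min,
                     "seed": seed}, index_label="sample")
        results["presence"] = pres

    if haplotypes is not None:
        anc = strains.ancestral_states(haplotypes, tie_break_tip=haplotypes.strains[0])
        afs_rows = []
        for s in samples:
            hist, edges = strains.derived_afs(counts, s, anc, n_bins=config.afs_bins)
            for k, c in enumerate(hist):
                afs_rows.append({"sample": s, "bin_low": round(edges[k], 4),
                                 "bin_high": round(edges[k + 1], 4), "count": int(c)})
        afs_table = pd.DataFrame(afs_rows)
        write_table(afs_table, outdir / "afs.tsv", "derived_afs",
                    {"n_bins": config.afs_bins, "tie_break_tip": haplotypes.strains[0],
                     "seed": seed})
        results["afs"] = afs_table

    # -- diversity ---------------------------------------------------------
    if tree is not None and frequencies is not None:
        alpha_rows = []
        for s in samples:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                alpha_rows.append({"sample": s, "pse": diversity.pse(tree, frequencies.loc[s])})
        alpha = pd.DataFrame(alpha_rows).set_index("sample")
        write_table(alpha, outdir / "alpha_diversity.tsv", "pse", {"seed": seed},
                    index_label="sample")
        results["alpha"] = alpha

        n = len(samples)
        beta = pd.DataFrame(np.zeros((n, n)), index=samples, columns=samples)
        for i in range(n):
            for j in range(i + 1, n):
                d = diversity.weighted_unifrac(
                    tree, frequencies.loc[samples[i]], frequencies.loc[samples[j]]
                )
                beta.iloc[i, j] = beta.iloc[j, i] = d
        write_table(beta, outdir / "beta_diversity.tsv", "weighted_unifrac",
                    {"seed": seed}, index_label="sample")
        results["beta"] = beta

        assoc_rows = []
        if len(samples) >= 4:
            finite = alpha["pse"].notna() & pi_table["pi"].notna()
            if finite.sum() >= 4:
                rho, rho2, p = diversity.rank_association(
                    pi_table.loc[finite, "pi"], alpha.loc[finite, "pse"]
                )
                assoc_rows.append({"test": "pi_vs_alpha_spearman", "statistic": rho,
                                   "rho2": rho2, "p": p})
            if len(samples) >= 4 and not fst_m.empty and np.isfinite(fst_m.values).all():
                stat, p = diversity.matrix_association(
                    fst_m, beta, n_perm=config.n_perm, seed=seed
                )
                assoc_rows.append({"test": "fst_vs_beta_mantel", "statistic": stat,
                                   "rho2": stat**2, "p": p})
            else:
                logger.warning("F_ST matrix has undefined entries; Mantel test skipped")
        assoc = pd.DataFrame(assoc_rows, columns=["test", "statistic", "rho2", "p"])
        write_table(assoc, outdir / "associations.tsv", "associations",
                    {"n_perm": config.n_perm, "seed": seed})
        results["associations"] = assoc

    # -- manifest ----------------------------------------------------------
    manifest = {
        "package": "strainpop",
        "version": __version__,
        "seed": seed,
        "mode": "simulate" if config.counts is None else "load",
        "n_samples": len(samples),
        "n_snvs": len(records),
        "genome_length": counts.genome_length,
        "thresholds": {
            "poly_lo": config.poly_lo, "poly_hi": config.poly_hi,
            "present_min": config.present_min, "dominant_min": config.dominant_min,
            "major_min": config.major_min, "afs_bins": config.afs_bins,
            "n_perm": config.n_perm,
        },
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results


def counts_positions(truth: simdata.SyntheticTruth) -> np.ndarray:
    return truth.all_variant_positions()
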