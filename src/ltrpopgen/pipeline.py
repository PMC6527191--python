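"""End-to-end per-lineage analysis pipeline and the K-selection scan.

Each lineage is processed fully independently: encode the RT alignment,
run replicate admixture MCMC over a K range, select K by the Evanno
delta-K, align and average the replicate runs at the selected K, classify
elements as admixed or full-membership, date insertions from their LTR
pairs, cluster families by the 80-80-80 rule, and compare insertion-time
distributions across groups.  Per-lineage seeds are derived from the
master seed and the lineage NAME (not input order), so permuting the
input leaves every per-lineage output unchanged.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clock import (
    DEFAULT_RATE,
    greedy_families,
    mean_pairwise_pdistance,
    pairwise_identity,
    time_of_insertion,
    undatable,
)
from .encoding import encode_alignment, write_genotype_tsv, write_structure_file
from .io import AlignedLineage, ElementRecord, bin_genome_density, read_aligned_fasta, read_element_table
from .mcmc import ModelConfig, run_mcmc
from .selection import align_runs, average_and_classify, evanno_delta_k
from .stats import GroupedAges, dunn_posthoc, kruskal_wallis, letter_display, mean_rank_order

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of one pipeline invocation.

    ``alignments`` maps lineage name to an aligned FASTA path (or directly
    to an :class:`AlignedLineage`).  K range, replicate runs and sweep
    counts default to desk scale; the genome-scale settings (K up to 10,
    10 runs, 50k+100k sweeps) are reachable through the same fields.
    """

    alignments: dict[str, str | Path | AlignedLineage]
    out_dir: str | Path
    element_table: str | Path | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    k_min: int = 1
    k_max: int = 6
    runs_per_k: int = 5
    burn_in: int = 5_000
    iterations: int = 10_000
    frequency_model: str = "correlated"
    lam: float = 1.0
    cutoff: float = 0.01
    rate: float = DEFAULT_RATE
    alpha_level: float = 0.05
    window_size_bp: int = 5_000_000
    seed: int = 0

    def k_values(self) -> list[int]:
        return list(range(self.k_min, self.k_max + 1))


def lineage_seed_sequence(master_seed: int, lineage_name: str) -> np.random.SeedSequence:
    """Stable per-lineage seed chain, independent of input order."""
    return np.random.SeedSequence(
        [int(master_seed), zlib.crc32(lineage_name.encode())]
    )


def scan_k(
    gm,
    k_values: list[int],
    runs_per_k: int,
    seed_seq: np.random.SeedSequence,
    burn_in: int = 5_000,
    iterations: int = 10_000,
    frequency_model: str = "correlated",
    lam: float = 1.0,
) -> tuple[dict[int, list[float]], dict[int, list[np.ndarray]]]:
    """Replicate MCMC runs over a K range.

    Returns per-K lists of ln Pr(X|K) estimates and of posterior-mean Q
    matrices, in run order.  Run seeds are drawn from ``seed_seq`` in a
    fixed (K, run) order, each below 2**31.
    """
    rng = np.random.default_rng(seed_seq)
    lnp_by_k: dict[int, list[float]] = {}
    q_by_k: dict[int, list[np.ndarray]] = {}
    for K in k_values:
        lnp_by_k[K] = []
        q_by_k[K] = []
        for _ in range(runs_per_k):
            cfg = ModelConfig(
                K=K,
                burn_in=burn_in,
                iterations=iterations,
                frequency_model=frequency_model,
                lam=lam,
                seed=int(rng.integers(1, 2**31 - 1)),
            )
            run = run_mcmc(gm, cfg)
            lnp_by_k[K].append(run.ln_prob_data)
            q_by_k[K].append(run.q_mean)
    return lnp_by_k, q_by_k


def _fmt(x: float, nd: int = 6) -> str:
    return f"{x:.{nd}g}"


def _lineage_records(
    records: dict[str, ElementRecord], lineage: str
) -> dict[str, ElementRecord]:
    return {
        eid: r for eid, r in records.items() if r.lineage_name == lineage
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full per-lineage analysis and write report files.

    Writes, per lineage: the genotype matrix (classic format + TSV), per-K
    run summaries, the Evanno table, averaged memberships with the
    admixed / full-membership classification, insertion ages, family
    assignments and a group-statistics table; plus a cross-lineage summary
    and, when coordinates are available, chromosome density profiles.
    Returns the results as a nested dict (also written as JSON).
    """
    ks = config.k_values()
    if len(ks) < 3:
        raise ValueError("delta-K needs >= 3 K values")
    if config.runs_per_k < 2:
        raise ValueError("delta-K needs >= 2 runs per K")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info(
        "pipeline: K=%d..%d runs=%d sweeps=%d+%d model=%s lambda=%g "
        "cutoff=%g rate=%g alpha=%g window=%d seed=%d",
        config.k_min, config.k_max, config.runs_per_k, config.burn_in,
        config.iterations, config.frequency_model, config.lam, config.cutoff,
        config.rate, config.alpha_level, config.window_size_bp, config.seed,
    )

    records: dict[str, ElementRecord] = {}
    if config.element_table is not None:
        records = read_element_table(config.element_table)

    results: dict = {"lineages": {}, "parameters": {
        "k_min": config.k_min, "k_max": config.k_max,
        "runs_per_k": config.runs_per_k, "burn_in": config.burn_in,
        "iterations": config.iterations,
        "frequency_model": config.frequency_model, "lam": config.lam,
        "cutoff": config.cutoff, "rate": config.rate,
        "alpha_level": config.alpha_level,
        "window_size_bp": config.window_size_bp, "seed": config.seed,
    }}
    summary_rows: list[list[str]] = []

    for lineage in sorted(config.alignments):
        src = config.alignments[lineage]
        aln = src if isinstance(src, AlignedLineage) else read_aligned_fasta(src, lineage)
        ldir = out_dir / lineage
        ldir.mkdir(parents=True, exist_ok=True)
        lres = _run_lineage(aln, config, ldir, _lineage_records(records, lineage))
        results["lineages"][lineage] = lres
        summary_rows.append([
            lineage,
            str(aln.n_elements),
            str(lres["n_loci"]),
            str(lres["selected_k"]),
            str(lres["n_admixed"]),
            str(lres["n_full_membership"]),
            str(lres["n_families"]) if lres["n_families"] is not None else "NA",
            lres["mean_length"], lres["sd_length"],
            _fmt(lres["pdistance_mean"]), _fmt(lres["pdistance_sd"]),
        ])

    # cross-lineage summary (counts and mean +/- SD sequence lengths)
    with open(out_dir / "summary.tsv", "w") as fh:
        fh.write("lineage\tn_elements\tn_loci\tselected_k\tn_admixed\t"
                 "n_full_membership\tn_families\tmean_length_bp\tsd_length_bp\t"
                 "pdistance_mean\tpdistance_sd\n")
        for row in summary_rows:
            fh.write("\t".join(row) + "\n")

    if config.chrom_lengths and records:
        profiles = bin_genome_density(
            records, config.chrom_lengths, config.window_size_bp
        )
        with open(out_dir / "density.tsv", "w") as fh:
            fh.write("chromosome\twindow\tstart\tend\tcount\n")
            for chrom in sorted(profiles):
                prof = profiles[chrom]
                for w, c in enumerate(prof.counts):
                    start = 1 + w * prof.window_size_bp
                    end = min((w + 1) * prof.window_size_bp, prof.chrom_length)
                    fh.write(f"{chrom}\t{w + 1}\t{start}\t{end}\t{int(c)}\n")
        results["density"] = {
            chrom: [int(c) for c in profiles[chrom].counts] for chrom in profiles
        }

    with open(out_dir / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    return results


def _run_lineage(
    aln: AlignedLineage,
    config: PipelineConfig,
    ldir: Path,
    records: dict[str, ElementRecord],
) -> dict:
    lineage = aln.lineage_name
    seed_seq = lineage_seed_sequence(config.seed, lineage)
    gm = encode_alignment(aln)
    write_structure_file(gm, ldir / "genotypes.str")
    write_genotype_tsv(gm, ldir / "genotypes.tsv")

    lnp_by_k, q_by_k = scan_k(
        gm, config.k_values(), config.runs_per_k, seed_seq,
        burn_in=config.burn_in, iterations=config.iterations,
        frequency_model=config.frequency_model, lam=config.lam,
    )
    with open(ldir / "runs.json", "w") as fh:
        json.dump(
            {str(k): [float(v) for v in vals] for k, vals in lnp_by_k.items()},
            fh, indent=1, sort_keys=True,
        )

    tab = evanno_delta_k(lnp_by_k)
    with open(ldir / "evanno.json", "w") as fh:
        json.dump({
            "k": tab.k_values,
            "mean_lnp": {str(k): tab.mean_lnp[k] for k in tab.k_values},
            "sd_lnp": {str(k): tab.sd_lnp[k] for k in tab.k_values},
            "l_prime": {str(k): tab.l_prime[k] for k in tab.l_prime},
            "l_second": {str(k): tab.l_second[k] for k in tab.l_second},
            "delta_k": {str(k): tab.delta_k[k] for k in tab.delta_k},
            "selected_k": tab.selected_k,
        }, fh, indent=1, sort_keys=True)

    aligned, _ = align_runs(q_by_k[tab.selected_k])
    profile = average_and_classify(aligned, gm.element_ids, config.cutoff)
    with open(ldir / "membership.tsv", "w") as fh:
        kcols = "\t".join(f"cluster{k + 1}" for k in range(tab.selected_k))
        fh.write(f"element_id\t{kcols}\tassigned\tclassification\n")
        for i, eid in enumerate(profile.element_ids):
            qrow = "\t".join(_fmt(v) for v in profile.q_mean[i])
            assigned = ",".join(
                str(k + 1) for k in profile.assigned_clusters[i]
            )
            fh.write(f"{eid}\t{qrow}\t{assigned}\t{profile.classification[i]}\n")

    # insertion dating from LTR pairs; elements without a pair are flagged
    ages = []
    for eid in gm.element_ids:
        rec = records.get(eid)
        if rec is not None and rec.has_ltr_pair:
            ident, _, _ = pairwise_identity(rec.ltr5, rec.ltr3)
            ages.append(time_of_insertion(ident, config.rate, element_id=eid))
        else:
            ages.append(undatable(eid, config.rate))

    # family clustering on RT nucleotide sequences when provided
    rt_seqs = {
        eid: records[eid].rt_nt
        for eid in gm.element_ids
        if eid in records and records[eid].rt_nt
    }
    families = greedy_families(rt_seqs) if rt_seqs else None
    with open(ldir / "ages.tsv", "w") as fh:
        fh.write("element_id\tidentity\tdivergence\tage_years\tage_my\tfamily\n")
        for age in ages:
            fam = ""
            if families is not None and age.element_id in families.family_of:
                fam = str(families.family_of[age.element_id] + 1)
            if age.dating_unavailable:
                fh.write(f"{age.element_id}\tNA\tNA\tNA\tNA\t{fam}\n")
            else:
                fh.write(
                    f"{age.element_id}\t{_fmt(age.identity)}\t"
                    f"{_fmt(age.divergence)}\t{_fmt(age.age_years)}\t"
                    f"{age.age_my:.2f}\t{fam}\n"
                )

    group_stats = _group_statistics(profile, ages, config.alpha_level, ldir)

    mean_pd, sd_pd = mean_pairwise_pdistance(aln.rows)

    lengths = [
        float(len(s))
        for eid in gm.element_ids if eid in records
        for s in (records[eid].ltr5, records[eid].ltr3, records[eid].rt_nt)
        if s
    ]
    mean_len = _fmt(float(np.mean(lengths))) if lengths else "NA"
    sd_len = (
        _fmt(float(np.std(lengths, ddof=1))) if len(lengths) > 1 else "NA"
    )

    n_admixed = profile.classification.count("admixed")
    return {
        "n_elements": aln.n_elements,
        "n_loci": gm.n_loci,
        "selected_k": tab.selected_k,
        "delta_k": {str(k): tab.delta_k[k] for k in tab.delta_k},
        "n_admixed": n_admixed,
        "n_full_membership": aln.n_elements - n_admixed,
        "n_families": families.n_families if families is not None else None,
        "n_dated": sum(1 for a in ages if not a.dating_unavailable),
        "pdistance_mean": mean_pd,
        "pdistance_sd": sd_pd,
        "mean_length": mean_len,
        "sd_length": sd_len,
        "group_stats": group_stats,
    }


def _group_statistics(profile, ages, alpha_level: float, ldir: Path) -> dict:
    """Insertion-time comparison across full-membership clusters + admixed."""
    age_by_id = {a.element_id: a for a in ages}
    groups: dict[str, list[float]] = {}
    for i, eid in enumerate(profile.element_ids):
        a = age_by_id[eid]
        if a.dating_unavailable:
            continue
        if profile.classification[i] == "admixed":
            label = "admixed"
        else:
            label = f"cluster{profile.assigned_clusters[i][0] + 1}"
        groups.setdefault(label, []).append(a.age_years)
    groups = {g: v for g, v in groups.items() if v}
    out: dict = {"groups": {}}
    letters = {}
    h = p = None
    if len(groups) >= 2 and sum(len(v) for v in groups.values()) >= 3:
        grouped = GroupedAges(groups)
        h, df, p = kruskal_wallis(grouped)
        pairs = dunn_posthoc(grouped, alpha=alpha_level)
        display = letter_display(
            {pair: pv for pair, (_, pv) in pairs.items()},
            group_order=mean_rank_order(grouped),
            alpha=alpha_level,
        )
        letters = display.letters
        out["kruskal_wallis"] = {"H": h, "df": df, "p": p}
    with open(ldir / "group_stats.tsv", "w") as fh:
        fh.write("group\tn\tmean_my\tsd_my\tletters\n")
        all_ages: list[float] = []
        for g in sorted(groups):
            vals = np.asarray(groups[g])
            all_ages.extend(groups[g])
            sd = float(vals.std(ddof=1)) / 1e6 if len(vals) > 1 else 0.0
            fh.write(
                f"{g}\t{len(vals)}\t{vals.mean() / 1e6:.2f}\t{sd:.2f}\t"
                f"{letters.get(g, 'a')}\n"
            )
            out["groups"][g] = {
                "n": int(len(vals)),
                "mean_my": float(vals.mean() / 1e6),
                "sd_my": sd,
                "letters": letters.get(g, "a"),
            }
        if all_ages:
            arr = np.asarray(all_ages)
            sd = float(arr.std(ddof=1)) / 1e6 if len(arr) > 1 else 0.0
            fh.write(
                f"all\t{len(arr)}\t{arr.mean() / 1e6:.2f}\t{sd:.2f}\t\n"
            )
    return out
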