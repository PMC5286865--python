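"""High-level workflows tying the modules into reproducible analyses.

These are the entry points the CLI (and the examples) call: per-region
leave-one-out scoring, anchor-aligned profile building, Z-scoring against
null ensembles, real-vs-randomized paired tests, expression correlation
batches, and the sequencing-error robustness check.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import arsi_scores_leave_one_out, simulate_read_errors
from .expression import (compare_groups, spearman_corr, partial_spearman,
                         split_high_low)
from .null_models import (ConsensusSpec, PairedTestResult, ZProfile,
                          mean_anchor_profiles, paired_real_vs_random_test,
                          randomize_genome, randomize_parts, zscore_profile)
from .profiles import WindowParams
from .sequence_io import (GeneModel, GeneParts, extract_regions, gene_parts,
                          region_elements)

logger = logging.getLogger(__name__)

DEFAULT_REGIONS = ("five_utr", "orf", "intron", "three_utr")


def parts_from_files(genome: dict[str, str],
                     models: Sequence[GeneModel]) -> list[GeneParts]:
    return [gene_parts(genome, m) for m in models]


def score_regions(parts_list: Sequence[GeneParts],
                  kinds: Sequence[str] = DEFAULT_REGIONS,
                  exclusion: str = "gene",
                  utr_fallback: Mapping[str, dict[str, str]] | None = None,
                  ) -> pd.DataFrame:
    """Leave-one-out ARSI per element, one region kind at a time.

    Each region kind uses the region-matched reference set (all elements
    of that kind in the genome, excluding the query's gene).  Returns a
    tidy frame: element_id, gene_id, region, length_nt, arsi.
    """
    rows = []
    for kind in kinds:
        fb = utr_fallback.get(kind) if utr_fallback else None
        elements = region_elements(list(parts_list), kind, utr_fallback=fb)
        if len(elements) < 2:
            logger.warning("region %s has %d element(s); skipped",
                           kind, len(elements))
            continue
        for s in arsi_scores_leave_one_out(elements, exclusion=exclusion):
            rows.append((s.element_id, s.gene_id, kind, s.length, s.value))
    return pd.DataFrame(rows, columns=["element_id", "gene_id", "region",
                                       "length_nt", "arsi"])


def flank_regions(genome: dict[str, str], models: Sequence[GeneModel],
                  flank_length: int = 250, exclusion: str = "gene") -> pd.DataFrame:
    """Leave-one-out ARSI of the fixed-length upstream/downstream flanks."""
    rows = []
    for kind in ("upstream_flank", "downstream_flank"):
        elements = []
        for m in models:
            rs = extract_regions(genome, m, flank_length)
            if kind in rs:
                elements.append((f"{m.gene_id}|{kind}", m.gene_id, rs[kind]))
        if len(elements) < 2:
            continue
        for s in arsi_scores_leave_one_out(elements, exclusion=exclusion):
            rows.append((s.element_id, s.gene_id, kind, s.length, s.value))
    return pd.DataFrame(rows, columns=["element_id", "gene_id", "region",
                                       "length_nt", "arsi"])


def real_vs_random(parts_list: Sequence[GeneParts], kind: str,
                   scheme: Sequence[str] = ("codons", "introns", "utrs"),
                   seed: int = 0,
                   consensus: ConsensusSpec = ConsensusSpec(),
                   exclusion: str = "gene") -> PairedTestResult:
    """Paired Wilcoxon test of real scores vs one matched randomization."""
    real = score_regions(parts_list, [kind], exclusion=exclusion)
    rparts = randomize_parts(parts_list, scheme, seed=seed, consensus=consensus)
    rand = score_regions(rparts, [kind], exclusion=exclusion)
    merged = real.merge(rand, on="element_id", suffixes=("_real", "_rand"))
    return paired_real_vs_random_test(merged["arsi_real"], merged["arsi_rand"])


def zscore_profiles(parts_list: Sequence[GeneParts],
                    params: WindowParams = WindowParams(),
                    anchors: Sequence[str] = ("orf_start",),
                    scheme: Sequence[str] = ("codons", "introns", "utrs"),
                    R: int = 50, seed: int = 0,
                    consensus: ConsensusSpec = ConsensusSpec(),
                    exclusion: str = "gene") -> dict[str, ZProfile]:
    """Anchor-aligned Z-score profiles of the real genome against R nulls."""
    real = mean_anchor_profiles(list(parts_list), params, anchors,
                                exclusion=exclusion)
    ens = randomize_genome(parts_list, scheme, R=R, seed=seed,
                           params=params, anchors=anchors,
                           consensus=consensus, exclusion=exclusion)
    return {a: zscore_profile(real[a], ens) for a in anchors}


def correlate_with_expression(scores: pd.DataFrame, expr: pd.DataFrame,
                              column: str = "mrna",
                              control_length: bool = False) -> pd.DataFrame:
    """Per-region Spearman (optionally length-controlled) with expression.

    ``scores`` is the tidy frame from :func:`score_regions`; gene-level
    scores average a gene's elements within each region.
    """
    rows = []
    for kind, sub in scores.groupby("region"):
        per_gene = sub.groupby("gene_id").agg(
            arsi=("arsi", "mean"), length_nt=("length_nt", "mean"))
        joined = per_gene.join(expr[column]).dropna()
        if len(joined) < 4:
            continue
        if control_length:
            res = partial_spearman(joined["arsi"], joined[column],
                                   {"length": joined["length_nt"]},
                                   pair=("arsi", column))
        else:
            res = spearman_corr(joined["arsi"], joined[[column]], column)
        rows.append((kind, res.rho, res.p_value, res.n,
                     ",".join(res.controls)))
    return pd.DataFrame(rows, columns=["region", "rho", "p", "n", "controls"])


def high_low_comparison(scores: pd.DataFrame, expr: pd.DataFrame,
                        column: str = "mrna", policy: str = "median",
                        ) -> pd.DataFrame:
    """Per-region high-vs-low expression rank-sum comparisons."""
    high, low = split_high_low(expr, column, policy=policy)
    rows = []
    for kind, sub in scores.groupby("region"):
        per_gene = sub.groupby("gene_id")["arsi"].mean()
        try:
            cmp = compare_groups(per_gene, high, low)
        except ValueError:
            continue
        rows.append((kind, cmp.statistic, cmp.p_value,
                     cmp.median_high, cmp.median_low, cmp.n_high, cmp.n_low))
    return pd.DataFrame(rows, columns=["region", "statistic", "p",
                                       "median_high", "median_low",
                                       "n_high", "n_low"])


def error_robustness(parts_list: Sequence[GeneParts], kind: str = "orf",
                     error_rate: float = 1e-3, n_replicates: int = 10,
                     seed: int = 0, exclusion: str = "gene") -> list[float]:
    """Spearman between leave-one-out scores before/after sequencing errors.

    Each replicate independently mutates every element at ``error_rate``
    and re-scores the mutated genome; returns one rho per replicate.
    """
    elements = region_elements(list(parts_list), kind)
    base = arsi_scores_leave_one_out(elements, exclusion=exclusion)
    base_vals = np.array([s.value for s in base])
    rhos = []
    for r in range(n_replicates):
        mutated = simulate_read_errors([seq for _, _, seq in elements],
                                       error_rate, seed=np.random.SeedSequence(
                                           [int(seed), r]).generate_state(1)[0] % (2**31))
        mels = [(eid, gid, mseq) for (eid, gid, _), mseq in zip(elements, mutated)]
        ms = arsi_scores_leave_one_out(mels, exclusion=exclusion)
        rho, _ = stats.spearmanr(base_vals, [s.value for s in ms])
        rhos.append(float(rho))
    return rhos
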