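"""Orchestration: evaluate marker combinations end to end.

For each requested marker combination the pipeline concatenates the
selected alignments (union of accessions, gap-filled), builds the K2P
distance matrix, summarises the barcoding gap, reconstructs UPGMA and
NJ trees with bootstrap supports, scores species monophyly, and runs
the three leave-one-out identification criteria.  Output is a single
EvaluationReport plus four TSV tables (marker profile, gap statistics,
resolution rates, identification success).
"""

from __future__ import annotations

import itertools
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignments import MarkerAlignment, MultiMarkerDataset, concatenate_markers
from .distances import (
    DistanceMatrix,
    GapSummary,
    build_distance_matrix,
    format_pvalue,
    gap_summary,
    partition_distances,
)
from .identification import CRITERIA, SuccessRates, identification_success_rates
from .io import write_newick, write_tsv
from .trees import ResolutionReport, bootstrap_supports, resolution_rates

__all__ = [
    "EvaluationReport",
    "marker_profile",
    "evaluate_combinations",
    "standard_combinations",
    "write_report",
]


def marker_profile(alignment: MarkerAlignment) -> dict:
    """Per-marker summary: length, individuals, variable/informative sites.

    A *variable* site has >= 2 distinct unambiguous bases among its
    non-gap residues; a *parsimony-informative* site has >= 2 distinct
    bases each present in >= 2 sequences.
    """
    from .distances import encode_sequences

    codes = encode_sequences([rec.residues for rec in alignment])
    n_var = 0
    n_inf = 0
    for col in codes.T:
        bases = col[col < 4]
        if bases.size == 0:
            continue
        counts = np.bincount(bases, minlength=4)
        present = counts[counts > 0]
        if present.size >= 2:
            n_var += 1
            if (present >= 2).sum() >= 2:
                n_inf += 1
    return {
        "marker": alignment.marker,
        "aligned_length": alignment.length,
        "n_individuals": len(alignment),
        "n_variable_sites": n_var,
        "n_parsimony_informative_sites": n_inf,
    }


def standard_combinations(markers: Sequence[str]) -> list[list[str]]:
    """The conventional 22-row combination set for a five-marker panel.

    All singles and pairs, the triples and quadruples anchored on the
    first two (core) markers, and the full five-marker set.  For panels
    of other sizes, falls back to all non-empty subsets.
    """
    markers = list(markers)
    if len(markers) != 5:
        return [list(c) for r in range(1, len(markers) + 1)
                for c in itertools.combinations(markers, r)]
    core = markers[:2]
    rest = markers[2:]
    combos: list[list[str]] = [[m] for m in markers]
    combos += [list(c) for c in itertools.combinations(markers, 2)]
    combos += [core + [m] for m in rest]
    combos += [core + list(c) for c in itertools.combinations(rest, 2)]
    combos.append(list(markers))
    return combos


def _drop_undefined(dm_aln: MarkerAlignment) -> tuple[MarkerAlignment, list[str]]:
    """Drop accessions until the combo's distance matrix is fully defined.

    Greedy: repeatedly remove the accession involved in the most
    undefined pairs (lexicographic tie-break).  Returns the possibly
    reduced alignment and the list of dropped accessions.
    """
    aln = dm_aln
    dropped: list[str] = []
    while True:
        dm = build_distance_matrix(aln)
        if dm.all_defined:
            return aln, dropped
        undef = ~dm.defined
        np.fill_diagonal(undef, False)
        counts = undef.sum(axis=1)
        worst = max(range(dm.n), key=lambda i: (counts[i], dm.labels[i]))
        victim = dm.labels[worst]
        dropped.append(victim)
        records = [r for r in aln.records if r.accession_id != victim]
        if len(records) < 2:
            raise ValueError("too few accessions with defined distances")
        aln = MarkerAlignment(marker=aln.marker, records=records, blocks=aln.blocks)


@dataclass
class EvaluationReport:
    """Full multi-combination evaluation output."""

    marker_profile: list[dict]
    gap: dict[str, GapSummary]
    resolution: list[ResolutionReport]
    identification: list[SuccessRates]
    trees: dict[tuple[str, str], object] = field(default_factory=dict)
    skipped_combos: list[tuple[str, str]] = field(default_factory=list)
    dropped_accessions: dict[str, list[str]] = field(default_factory=dict)


def evaluate_combinations(
    dataset: MultiMarkerDataset,
    combos: Sequence[Sequence[str]] | None = None,
    methods: Sequence[str] = ("upgma", "nj"),
    criteria: Sequence[str] = CRITERIA,
    n_boot: int = 1000,
    support_threshold: int = 70,
    percentile: float = 95.0,
    bin_width: float = 0.005,
    seed: int = 0,
) -> EvaluationReport:
    """Run the full evaluation over marker combinations.

    Deterministic given ``seed``: each (combo, method) bootstrap gets a
    seed spawned from one master SeedSequence.  Combos whose accession
    sets leave fewer than two usable sequences are skipped with a
    warning.
    """
    if combos is None:
        combos = standard_combinations(dataset.markers)
    combos = [list(c) for c in combos]
    if not combos:
        raise ValueError("combos must be non-empty")

    profile = [marker_profile(dataset.alignments[m]) for m in dataset.markers]

    gap: dict[str, GapSummary] = {}
    for m in dataset.markers:
        if len(dataset.alignments[m]) < 2:
            continue
        dm = build_distance_matrix(dataset.alignments[m])
        intra, inter = partition_distances(dm, dataset.species_of)
        if inter:
            gap[m] = gap_summary(intra, inter, bin_width=bin_width)

    master = np.random.SeedSequence(seed)
    boot_seeds = master.spawn(len(combos) * len(methods))

    resolution: list[ResolutionReport] = []
    identification: list[SuccessRates] = []
    trees: dict[tuple[str, str], object] = {}
    skipped: list[tuple[str, str]] = []
    dropped_log: dict[str, list[str]] = {}

    for ci, combo in enumerate(combos):
        name = "+".join(combo)
        aln = concatenate_markers(dataset, combo)
        if len(aln) < 2:
            warnings.warn(f"combo {name}: fewer than 2 accessions; skipped")
            skipped.append((name, "fewer than 2 accessions"))
            continue
        try:
            aln, dropped = _drop_undefined(aln)
        except ValueError as exc:
            warnings.warn(f"combo {name}: {exc}; skipped")
            skipped.append((name, str(exc)))
            continue
        if dropped:
            warnings.warn(
                f"combo {name}: dropped {len(dropped)} accession(s) with "
                f"undefined distances: {dropped[:5]}"
            )
            dropped_log[name] = dropped

        for mi, method in enumerate(methods):
            boot_seed = boot_seeds[ci * len(methods) + mi]
            tree = bootstrap_supports(
                aln, method=method, n_reps=n_boot,
                seed=int(boot_seed.generate_state(1)[0] % (2**31)),
            )
            trees[(name, method)] = tree
            resolution.append(
                resolution_rates(
                    tree,
                    dataset.species_of,
                    support_threshold=support_threshold,
                    combo=combo,
                    method=method,
                )
            )
        identification.append(
            identification_success_rates(
                aln,
                dataset.species_of,
                criteria=criteria,
                percentile=percentile,
                combo=combo,
            )
        )

    return EvaluationReport(
        marker_profile=profile,
        gap=gap,
        resolution=resolution,
        identification=identification,
        trees=trees,
        skipped_combos=skipped,
        dropped_accessions=dropped_log,
    )


def write_report(report: EvaluationReport, outdir: str, criteria: Sequence[str] = CRITERIA) -> None:
    """Write the four TSV tables (and Newick trees) for a report."""
    os.makedirs(outdir, exist_ok=True)
    write_tsv(
        os.path.join(outdir, "profile.tsv"),
        [
            "marker",
            "aligned_length",
            "n_individuals",
            "n_variable_sites",
            "n_parsimony_informative_sites",
        ],
        [
            [
                p["marker"],
                p["aligned_length"],
                p["n_individuals"],
                p["n_variable_sites"],
                p["n_parsimony_informative_sites"],
            ]
            for p in report.marker_profile
        ],
    )

    gap_rows = []
    for marker, g in report.gap.items():
        gap_rows.append(
            [
                marker,
                g.n_inter,
                g.n_intra,
                format_pvalue(g.median_p),
                "NA" if g.wilcoxon_W is None else f"{g.wilcoxon_W:.0f}",
                format_pvalue(g.wilcoxon_p),
                f"{g.mean_inter:.4f}",
                f"{g.range_inter[0]:.4f}-{g.range_inter[1]:.4f}",
                "NA" if g.mean_intra is None else f"{g.mean_intra:.4f}",
                "NA"
                if g.range_intra is None
                else f"{g.range_intra[0]:.4f}-{g.range_intra[1]:.4f}",
            ]
        )
    write_tsv(
        os.path.join(outdir, "gap.tsv"),
        [
            "marker",
            "n_inter",
            "n_intra",
            "median_p",
            "wilcoxon_W",
            "wilcoxon_p",
            "mean_inter",
            "range_inter",
            "mean_intra",
            "range_intra",
        ],
        gap_rows,
    )

    hist_rows = []
    for marker, g in report.gap.items():
        for k in range(len(g.histogram_inter)):
            hist_rows.append(
                [
                    marker,
                    f"{g.bin_edges[k]:.4f}",
                    f"{g.bin_edges[k + 1]:.4f}",
                    int(g.histogram_intra[k]),
                    int(g.histogram_inter[k]),
                ]
            )
    write_tsv(
        os.path.join(outdir, "gap_histogram.tsv"),
        ["marker", "bin_lo", "bin_hi", "n_intra", "n_inter"],
        hist_rows,
    )

    write_tsv(
        os.path.join(outdir, "resolution.tsv"),
        [
            "combo",
            "method",
            "n_species",
            "n_monophyletic",
            "n_supported",
            "rate",
            "rate_supported",
        ],
        [
            [
                "+".join(r.combo),
                r.method,
                r.n_species_evaluated,
                r.n_monophyletic,
                r.n_monophyletic_supported,
                f"{r.rate:.1f}",
                f"{r.rate_supported:.1f}",
            ]
            for r in report.resolution
        ],
    )

    ident_rows = []
    for s in report.identification:
        row = ["+".join(s.combo)]
        for crit in criteria:
            row.append(f"{s.per_criterion[crit]['pct_correct']:.2f}")
        ident_rows.append(row)
    write_tsv(
        os.path.join(outdir, "identification.tsv"),
        ["combo"] + [f"pct_correct_{c}" for c in criteria],
        ident_rows,
    )

    tree_dir = os.path.join(outdir, "trees")
    os.makedirs(tree_dir, exist_ok=True)
    for (name, method), tree in report.trees.items():
        safe = name.replace("+", "_")
        write_newick(tree, os.path.join(tree_dir, f"{safe}.{method}.nwk"))
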