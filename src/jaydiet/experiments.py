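"""Desk-scale validation experiments over the synthetic generators.

Each function runs one self-contained experiment — taxonomic-rank recovery
under clean and collapsed barcode-gap geometries, cached/fresh ground-truth
recovery — and returns plain dictionaries of counts and fractions. They are
used by the validation tests, the acceptance script and the analysis
drivers, always recomputing from scratch for the given seed.
"""

from __future__ import annotations

from jaydiet import synthetic_data as sd
from jaydiet import taxonomy as tx
from jaydiet.cache_classifier import classify_dataset, sac_level_cached_presence
from jaydiet.diet_compilation import pct, tally
from jaydiet.fixtures import study_observations
from jaydiet.pipeline import PipelineConfig, run_qc
from jaydiet.read_qc import PrimerPair

PRIMER_F = "ACGTACGTAC"
PRIMER_R = "TGCATGCATG"


def rank_recovery(marker: str, intra: float, inter: float, n_taxa: int,
                  seed: int, seqs_per_taxon: int = 4, seq_length: int = 300,
                  reads_per_template: int = 2) -> dict:
    """Simulate a library and error-free reads, run the full QC + assignment
    chain, and score species recovery and assigned-rank composition.

    With a clean gap (intra << inter) assignments should recover the true
    species at species rank; with overlapping clusters (intra >= inter)
    every assignment should fall back to genus (COI-5P/ITS2) or
    genus/family (rbcLa).
    """
    ref_spec = sd.RefLibrarySpec(
        n_taxa=n_taxa, seqs_per_taxon=seqs_per_taxon, seq_length=seq_length,
        intra_divergence=intra, inter_divergence=inter, marker=marker,
        seed=seed)
    refs = sd.gen_reference_library(ref_spec)
    gap_results = tx.gap_analysis_all(refs)
    read_spec = sd.ReadSimSpec(
        reads_per_template=reads_per_template, error_rate=0.0,
        primer_forward=PRIMER_F, primer_reverse=PRIMER_R, seed=seed + 1)
    reads = sd.gen_reads(refs, read_spec)
    uniques, _ = run_qc(reads, PrimerPair(PRIMER_F, PRIMER_R),
                        PipelineConfig(min_reads=1))
    assignments = tx.assign_queries(uniques, refs, gap_results, marker)
    truth = {r.degapped: r.taxon for r in refs}
    n = len(assignments)
    correct_species = sum(
        a.assigned_rank == "species" and
        a.assigned_taxon == truth[u.sequence].species
        for u, a in zip(uniques, assignments))
    ranks = [a.assigned_rank for a in assignments]
    return {
        "n_queries": n,
        "frac_true_species": correct_species / n,
        "frac_species_rank": ranks.count("species") / n,
        "frac_genus_rank": ranks.count("genus") / n,
        "frac_family_rank": ranks.count("family") / n,
        "frac_genus_or_family": (ranks.count("genus") +
                                 ranks.count("family")) / n,
    }


def classifier_recovery(n_items: int, cached_fraction: float, seed: int
                        ) -> dict:
    """Generate observations with hidden ground truth, classify them, and
    score recovery of construction-guaranteed cached and fresh items."""
    sim = sd.gen_observations(sd.ObservationSimSpec(
        n_items=n_items, cached_fraction=cached_fraction, seed=seed))
    out, _ = classify_dataset(sim.observations, sim.profiles, sim.snow)
    merged = out.set_index("obs_id").join(sim.ground_truth)
    cached = merged[merged["cached"]]
    fresh = merged[~merged["cached"]]
    return {
        "n_items": int(len(merged)),
        "n_true_cached": int(len(cached)),
        "frac_cached_recovered":
            float((cached["designation"] == "likely_cached").mean()),
        "frac_fresh_firing_criteria":
            float((fresh["criteria_fired"] != "").mean()),
        "recovered_cached_fraction":
            float((merged["designation"] == "likely_cached").mean()),
    }


def fixture_summary() -> dict:
    """All printed-figure quantities recomputed from the packaged fixture."""
    df = study_observations()
    designated, summary = classify_dataset(df)
    by_method = {r["method"]: (int(r["count"]), int(r["pct"]))
                 for _, r in tally(df, ["method"]).iterrows()}
    do = df[df["method"] == "DO"]
    do_groups = {r["food_group"]: (int(r["count"]), int(r["pct"]))
                 for _, r in tally(do, ["food_group"]).iterrows()}
    do_vert = do[(do["food_group"] == "V") & (do["subcategory"] != "")]
    vert_sub = {r["subcategory"]: (int(r["count"]), int(r["pct"]))
                for _, r in tally(do_vert, ["subcategory"]).iterrows()}
    sac = sac_level_cached_presence(designated)
    return {
        "n_total": int(len(df)),
        "by_method": by_method,
        "do_food_groups": do_groups,
        "do_vertebrate_subcategories": vert_sub,
        "winter_adult": summary["winter_adult"],
        "nestling": summary["nestling"],
        "sac_presence": {"num": sac[0], "denom": sac[1],
                         "pct": pct(sac[0], sac[1])},
    }
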