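"""End-to-end mining orchestration.

Stage order follows the retrieval procedure: profile scan and family
assignment, the 6-9 TM-segment filter (whitelist-aware), within-proteome
redundancy collapse, dual-model scatter + motif scan + reclassification
on the Rhodopsin/cAMP boundary, N-terminal domain annotation, per-family
consensus emission, and an anchored-MSA NJ tree with bootstrap support
used to verify that the Rhodopsin and cAMP groups separate. Every input
sequence ends with exactly one disposition: unclassified, tm_filtered,
duplicate, or reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .classify import (DEFAULT_MOTIFS, FamilyCall, MotifDef, assign_family,
                       calls_to_frame, find_motifs, reclassify,
                       scatter_coordinates)
from .config import RunConfig
from .domains import DomainArchitecture, annotate_nterm
from .hmm import (ProfileHMM, build_profile, emit_consensus,
                  scan_best_domains)
from .phylo import (AnchoredMSA, SupportTree, bootstrap_support,
                    hmm_anchored_msa, is_monophyletic)
from .redundancy import ClusterSet, cluster_at_threshold
from .seqio import SequenceRecord
from .topology import TMTopology, passes_tm_filter, predict_tm_segments

log = logging.getLogger("gpcrminer")


@dataclass
class MiningReport:
    """All pipeline outputs for one run."""

    calls: pd.DataFrame
    counts: pd.DataFrame
    dispositions: pd.DataFrame
    clusters: dict[str, ClusterSet]
    architectures: list[DomainArchitecture]
    consensus: dict[str, str]
    trees: dict[str, SupportTree]
    monophyly: dict[str, tuple[bool, float | None]]
    provenance: dict = field(default_factory=dict)


def run_mining(records: list[SequenceRecord],
               profiles: dict[str, ProfileHMM],
               cfg: RunConfig,
               domain_profiles: list[ProfileHMM] | None = None,
               motif_defs: tuple[MotifDef, ...] = DEFAULT_MOTIFS,
               anchor_model: str = "7tm_1",
               scatter_models: tuple[str, str] = ("7tm_1", "Dicty_CAR"),
               bootstrap_reps: int = 100,
               known_accessions: set[str] | None = None) -> MiningReport:
    """Run the full mining pipeline over tagged sequence records.

    ``profiles`` maps model names to calibrated family profiles;
    ``known_accessions`` optionally excludes previously published ids so
    only novel sequences are reported.
    """
    for p in profiles.values():
        if not p.calibrated:
            raise ValueError(f"profile {p.name!r} must be calibrated")
    domain_profiles = domain_profiles or []
    known_accessions = known_accessions or set()

    by_species: dict[str, list[SequenceRecord]] = {}
    for r in records:
        by_species.setdefault(r.species or "unknown", []).append(r)

    disposition: dict[str, str] = {}
    calls: dict[str, FamilyCall] = {}
    topologies: dict[str, TMTopology] = {}
    survivors: dict[str, SequenceRecord] = {}
    clusters: dict[str, ClusterSet] = {}

    for species, members in sorted(by_species.items()):
        db_size = len(members)
        log.info("scan: %s (%d sequences)", species, db_size)
        classified: list[SequenceRecord] = []
        for rec in members:
            if rec.id in known_accessions:
                disposition[rec.id] = "known"
                continue
            hits = scan_best_domains(profiles.values(), rec,
                                     report_cutoff=cfg.report_cutoff,
                                     db_size=db_size)
            call = assign_family(hits, cfg)
            call.target_id = rec.id
            calls[rec.id] = call
            if call.family == "unclassified":
                disposition[rec.id] = "unclassified"
                continue
            top = predict_tm_segments(rec)
            topologies[rec.id] = top
            if (rec.id not in cfg.tm_whitelist
                    and not passes_tm_filter(top, cfg)):
                disposition[rec.id] = "tm_filtered"
                continue
            classified.append(rec)
        log.info("scan: %s -> %d classified, %d after TM filter",
                 species, sum(1 for r in members if r.id in calls
                              and calls[r.id].family != "unclassified"),
                 len(classified))
        cs = cluster_at_threshold(classified, cfg.redundancy_threshold)
        clusters[species] = cs
        reps = set(cs.representatives())
        for rec in classified:
            if rec.id in reps:
                disposition[rec.id] = "reported"
                survivors[rec.id] = rec
            else:
                disposition[rec.id] = "duplicate"

    # scatter, motifs and reclassification on the Rhodopsin/cAMP boundary
    ma, mb = scatter_models
    for rid, rec in survivors.items():
        call = calls[rid]
        top = topologies[rid]
        motifs = find_motifs(rec, top, motif_defs) if top.n_tm >= 6 else []
        if (ma in profiles and mb in profiles
                and call.best_model in scatter_models):
            coords, ambiguous = scatter_coordinates(
                rec, profiles[ma], profiles[mb],
                db_size=len(by_species[rec.species or "unknown"]), cfg=cfg)
            call.scatter = coords
            call.ambiguous = ambiguous
        calls[rid] = reclassify(call, motifs, cfg)

    # N-terminal domain architecture
    architectures = [
        annotate_nterm(rec, topologies[rid], domain_profiles,
                       cutoff=cfg.domain_evalue_cutoff)
        for rid, rec in sorted(survivors.items())
        if topologies[rid].n_tm >= 1
    ]

    # per-family consensus + trees
    by_family: dict[str, list[SequenceRecord]] = {}
    for rid, rec in survivors.items():
        by_family.setdefault(calls[rid].family, []).append(rec)
    consensus: dict[str, str] = {}
    trees: dict[str, SupportTree] = {}
    monophyly: dict[str, tuple[bool, float | None]] = {}
    model_of_family = {"Rhodopsin": "7tm_1", "Adhesion": "7tm_2",
                      "Glutamate": "7tm_3", "Frizzled": "Frizzled",
                      "cAMP": "Dicty_CAR"}
    for family, members in sorted(by_family.items()):
        model = model_of_family.get(family)
        if model is None or model not in profiles or len(members) < 2:
            continue
        msa = hmm_anchored_msa(profiles[model], sorted(
            members, key=lambda r: r.id))
        consensus[family] = emit_consensus(build_profile(
            msa.rows, name=f"{family}_consensus"))
    # joint tree on the scatter pair, anchored to the first scatter model
    pair_members = [r for fam in scatter_family_names(scatter_models)
                    for r in by_family.get(fam, [])]
    if len(pair_members) >= 4 and ma in profiles:
        msa = hmm_anchored_msa(profiles[ma],
                               sorted(pair_members, key=lambda r: r.id))
        tree = bootstrap_support(msa, n_reps=bootstrap_reps,
                                 seed=cfg.random_seed)
        trees["rhodopsin_camp"] = tree
        for fam in scatter_family_names(scatter_models):
            ids = {r.id for r in by_family.get(fam, [])}
            if 0 < len(ids) < len(tree.leaf_set):
                monophyly[fam] = is_monophyletic(tree, ids)

    call_frame = calls_to_frame([calls[rid] for rid in sorted(survivors)])
    species_of = {r.id: (r.species or "unknown") for r in records}
    call_frame.insert(1, "species",
                      [species_of[i] for i in call_frame["id"]])
    counts = (call_frame.groupby(["species", "family"])
              .size().rename("count").reset_index())
    dispositions = pd.DataFrame(
        [{"id": rid, "disposition": d}
         for rid, d in sorted(disposition.items())])
    provenance = {"config": vars(cfg).copy(),
                  "profiles": sorted(profiles),
                  "n_input": len(records)}
    return MiningReport(calls=call_frame, counts=counts,
                        dispositions=dispositions, clusters=clusters,
                        architectures=architectures, consensus=consensus,
                        trees=trees, monophyly=monophyly,
                        provenance=provenance)


def scatter_family_names(scatter_models: tuple[str, str]) -> tuple[str, str]:
    from .classify import MODEL_FAMILY
    return tuple(MODEL_FAMILY[m] for m in scatter_models)
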