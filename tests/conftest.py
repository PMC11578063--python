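"""Shared simulation fixtures (session-scoped: the pipelines are reused)."""

from __future__ import annotations

import pytest

import dehalopan as dp
from dehalopan.og_classification import align_proteins


def run_og_pipeline(sim: dp.SimulatedPangenome, bootstrap: int = 30, seed: int = 3):
    """Mine retained RdhA, build identity matrix, OGs, tree, curated OGs."""
    all_feats = [f for fs in sim.features.values() for f in fs]
    prots = {p.protein_id: p for ps in sim.proteins.values() for p in ps}
    cand = [prots[f.feature_id] for f in dp.select_rdha_features(all_feats)]
    cands = dp.screen_candidates(cand, all_feats)
    retained = [c.protein for c in cands if c.verdict == "retained"]
    ident = dp.identity_matrix(retained)
    part = dp.assign_ogs(ident)
    tree = dp.build_nj_tree(ident, alignment=align_proteins(retained),
                            bootstrap=bootstrap, seed=seed)
    curated = dp.curate_partition(part, tree, ident)
    return {
        "candidates": cands,
        "retained": retained,
        "identity": ident,
        "partition": part,
        "tree": tree,
        "curated": curated,
    }


@pytest.fixture(scope="session")
def small_sim() -> dp.SimulatedPangenome:
    return dp.simulate_pangenome(dp.FIXTURES["small"]())


@pytest.fixture(scope="session")
def medium_sim() -> dp.SimulatedPangenome:
    return dp.simulate_pangenome(dp.FIXTURES["medium"]())


@pytest.fixture(scope="session")
def island_sim() -> dp.SimulatedPangenome:
    return dp.simulate_pangenome(dp.FIXTURES["island"]())


@pytest.fixture(scope="session")
def hgt_sim() -> dp.SimulatedPangenome:
    return dp.simulate_pangenome(dp.FIXTURES["hgt-og"]())


@pytest.fixture(scope="session")
def medium_og(medium_sim):
    return run_og_pipeline(medium_sim)


@pytest.fixture(scope="session")
def hgt_og(hgt_sim):
    return run_og_pipeline(hgt_sim)


@pytest.fixture(scope="session")
def island_pipeline(island_sim):
    """Gene clusters, SCG map and delimited islands on the island fixture."""
    clusters = dp.cluster_genes(island_sim.proteins)
    gids = sorted(island_sim.genomes)
    scgs = dp.single_copy_core(clusters, gids)
    scg_map = {pid: c.cluster_id for c in scgs for _g, pid in c.members}
    islands = {}
    for g, _s, _e, _d in island_sim.truth.true_island:
        feats = island_sim.features[g]
        cargo = next(f for f in feats if f.feature_id.endswith("|isl000"))
        islands[g] = dp.delimit_island(
            (cargo.contig_id, cargo.start, cargo.end),
            island_sim.genomes[g], feats, scg_map,
        )
    return {"clusters": clusters, "scgs": scgs, "scg_map": scg_map,
            "islands": islands}


@pytest.fixture(scope="session")
def species_sim() -> dp.SimulatedPangenome:
    """9 genomes, 3 clades: within-clade ~99% identity, across ~92%."""
    return dp.simulate_pangenome(dp.SimConfig(seed=21))


@pytest.fixture(scope="session")
def species_ani(species_sim):
    return dp.ani_matrix(list(species_sim.genomes.values()))
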