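"""Determinism, closed-form properties and truth recovery of the generator."""

import networkx as nx
import numpy as np
import pytest
from scipy.stats import binom

from dupnet.io import read_bed_genes, read_gmt, read_scored_edge_list
from dupnet.network import clean
from dupnet.regions import map_regions, parse_region
from dupnet.synthetic import (
    SyntheticConfig,
    generate_dataset,
    generate_interactome,
    plant_disease_module,
    plant_enriched_library,
)

SMALL = SyntheticConfig(
    n_nodes=300, attachment=3, genes_per_region=6, disease_module_size=12,
    n_causal_seeds=4, n_terms=10, term_size=8, extra_association_rows=40,
)


class TestInteractome:
    def test_same_seed_byte_identical(self, tmp_path):
        from dupnet.io import write_scored_edge_list

        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_scored_edge_list(generate_interactome(SMALL, 5), p1, dialect="hippie")
        write_scored_edge_list(generate_interactome(SMALL, 5), p2, dialect="hippie")
        assert p1.read_bytes() == p2.read_bytes()

    def test_edge_budget_closed_form(self):
        cfg = SyntheticConfig(n_nodes=500, attachment=3)
        edges = generate_interactome(cfg, 1)
        assert len(edges) == 3 * (500 - 3)

    def test_score_fraction_binomial(self):
        cfg = SyntheticConfig(n_nodes=1000, attachment=3)
        edges = generate_interactome(cfg, 2)
        n = len(edges)
        above = sum(1 for e in edges if e.score > 0.4)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.6)
        assert lo <= above <= hi

    def test_heavy_tailed_degrees(self):
        edges = generate_interactome(SyntheticConfig(n_nodes=1000, attachment=3), 3)
        G = clean(edges)
        degrees = sorted((d for _, d in G.degree()), reverse=True)
        assert degrees[0] > 10 * np.median(degrees)


class TestRegions:
    def test_truth_recovery_through_files(self, tmp_path):
        ds = generate_dataset(SMALL, seed=9)
        paths = ds.write(tmp_path)
        annotation = read_bed_genes(paths["annotation"])
        regions = []
        with open(paths["regions"]) as fh:
            for line in fh:
                label, text = line.strip().split("\t")
                regions.append(parse_region(text, label=label))
        mapped = map_regions(annotation, regions)
        assert {k: sorted(v) for k, v in mapped.items()} == ds.truth["regions"]

    def test_decoy_one_base_outside_excluded(self):
        ds = generate_dataset(SMALL, seed=9)
        mapped = map_regions(ds.annotations, ds.regions)
        decoys = {a.symbol for a in ds.annotations if a.symbol.startswith("DECOY")}
        lnc = {a.symbol for a in ds.annotations if a.symbol.startswith("LNC")}
        for genes in mapped.values():
            assert not genes & decoys
            assert not genes & lnc
        # the nearest decoy ends exactly one base before its region start
        for region in ds.regions:
            near = [
                a for a in ds.annotations
                if a.symbol.startswith("DECOY") and a.end == region.start - 1
            ]
            assert near, "expected a boundary decoy per region"

    def test_recovery_across_many_configs(self, rng):
        for _ in range(25):
            cfg = SyntheticConfig(
                n_nodes=int(rng.integers(100, 400)),
                attachment=int(rng.integers(2, 6)),
                n_regions=int(rng.integers(1, 4)),
                genes_per_region=int(rng.integers(3, 10)),
                disease_module_size=10,
                n_causal_seeds=3,
                n_terms=5,
                term_size=5,
            )
            ds = generate_dataset(cfg, seed=int(rng.integers(2**31)))
            mapped = map_regions(ds.annotations, ds.regions)
            assert {k: sorted(v) for k, v in mapped.items()} == ds.truth["regions"]


class TestDiseaseModule:
    def test_full_wiring_touches_every_causal_seed(self):
        cfg = SyntheticConfig(
            n_nodes=300, attachment=3, genes_per_region=6,
            disease_module_size=12, n_causal_seeds=4, wiring_prob=1.0,
        )
        ds = generate_dataset(cfg, seed=4)
        G = clean(ds.edges)
        module = set(ds.truth["module_genes"])
        for s in ds.truth["causal_seeds"]:
            assert any(m in G.neighbors(s) for m in module)

    def test_null_configuration_symmetric(self):
        cfg = SyntheticConfig(
            n_nodes=300, attachment=3, genes_per_region=6,
            disease_module_size=12, n_causal_seeds=4,
            wiring_prob=0.05, background_wiring_prob=0.05,
        )
        ds = generate_dataset(cfg, seed=5)
        # same wiring law for causal and non-causal: flag carries no signal
        assert ds.truth["causal_seeds"]
        assert set(ds.truth["causal_seeds"]).isdisjoint(ds.truth["noncausal_seeds"])

    def test_module_is_connected_and_disjoint_from_seeds(self):
        ds = generate_dataset(SMALL, seed=11)
        G = nx.Graph((r.gene_a, r.gene_b) for r in ds.edges)
        module = ds.truth["module_genes"]
        assert nx.is_connected(G.subgraph(module))
        seeds = {g for genes in ds.truth["regions"].values() for g in genes}
        assert seeds.isdisjoint(module)


class TestLibraryAndDiseases:
    def test_infinite_odds_term_inside_module(self):
        cfg = SyntheticConfig(
            n_nodes=300, attachment=3, genes_per_region=6,
            disease_module_size=12, n_causal_seeds=4, term_size=8,
            enrichment_odds=float("inf"), n_terms=5,
        )
        ds = generate_dataset(cfg, seed=6)
        planted = ds.library.terms[ds.truth["planted_term"]].genes
        assert planted <= set(ds.truth["module_genes"])

    def test_planted_disease_has_all_causal_seeds(self):
        ds = generate_dataset(SMALL, seed=12)
        planted = ds.truth["planted_disease"]
        genes_with_planted = {r.gene for r in ds.gene_disease if r.disease == planted}
        assert set(ds.truth["causal_seeds"]) <= genes_with_planted


class TestDatasetContract:
    def test_pure_function_of_config_and_seed(self, tmp_path):
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        generate_dataset(SMALL, seed=21).write(d1)
        generate_dataset(SMALL, seed=21).write(d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes(), f.name

    def test_all_files_parse_with_zero_skips(self, tmp_path):
        ds = generate_dataset(SMALL, seed=22)
        paths = ds.write(tmp_path)
        edges = read_scored_edge_list(paths["edges"], dialect="hippie")
        assert edges.skipped == 0
        assert len(edges) == len(ds.edges)
        assert len(read_bed_genes(paths["annotation"])) == len(ds.annotations)
        assert len(read_gmt(paths["gmt"])) == len(ds.library)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_nodes=5)
        with pytest.raises(ValueError):
            SyntheticConfig(wiring_prob=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(n_nodes=50, genes_per_region=20, disease_module_size=20)
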