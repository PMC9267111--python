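import numpy as np
import pandas as pd
import pytest

from cubkit.cub_metrics import rscu
from cubkit.genetic_code import RSCU_CODONS
from cubkit.similarity import (
    PcaProjection,
    SelectionCircle,
    cluster_circle,
    missing_trna_codon_report,
    per_virus_circle,
    read_trna_table,
    rscu_pca,
    select_similar_genes,
)


def random_rscu_frame(rng, n, prefix):
    data = rng.uniform(0, 2, size=(n, 59))
    return pd.DataFrame(data, index=[f"{prefix}{i}" for i in range(n)], columns=list(RSCU_CODONS))


def manual_projection(points, virus_ids):
    """Build a PcaProjection directly from given (pc1, pc2) coordinates."""
    scores = pd.DataFrame(points, columns=["pc1", "pc2"])
    ids = frozenset(scores.index)
    return PcaProjection(
        scores=scores,
        variance_explained=(0.6, 0.4),
        loadings=pd.DataFrame(np.zeros((59, 2)), index=list(RSCU_CODONS), columns=["pc1", "pc2"]),
        virus_ids=frozenset(virus_ids),
        host_ids=ids - frozenset(virus_ids),
    )


class TestRscuPca:
    def test_eigen_oracle(self):
        rng = np.random.default_rng(0)
        host = random_rscu_frame(rng, 3, "h")
        virus = random_rscu_frame(rng, 2, "v")
        proj = rscu_pca(host, virus)
        x = pd.concat([host, virus]).to_numpy()
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        order = np.argsort(evals)[::-1]
        for j in range(proj.scores.shape[1]):
            ref = xc @ evecs[:, order[j]]
            got = proj.scores.iloc[:, j].to_numpy()
            assert np.allclose(np.abs(got), np.abs(ref), atol=1e-8)

    def test_duplicated_rows_same_scores_and_variance(self):
        rng = np.random.default_rng(1)
        host = random_rscu_frame(rng, 5, "h")
        virus = random_rscu_frame(rng, 3, "v")
        host2 = pd.concat([host, host.set_axis([f"{i}_dup" for i in host.index])])
        virus2 = pd.concat([virus, virus.set_axis([f"{i}_dup" for i in virus.index])])
        p1 = rscu_pca(host, virus)
        p2 = rscu_pca(host2, virus2)
        assert np.allclose(p1.variance_explained[:4], p2.variance_explained[:4], atol=1e-9)
        for i in host.index:
            assert np.allclose(
                p2.scores.loc[i].to_numpy(), p2.scores.loc[f"{i}_dup"].to_numpy()
            )
            assert np.allclose(
                p1.scores.loc[i].to_numpy(), p2.scores.loc[i].to_numpy(), atol=1e-8
            )

    def test_rank_one_matrix(self):
        rng = np.random.default_rng(2)
        direction = rng.uniform(-1, 1, 59)
        coeffs = rng.uniform(-2, 2, 8)
        data = 1.0 + np.outer(coeffs, direction)
        host = pd.DataFrame(data[:5], index=[f"h{i}" for i in range(5)], columns=list(RSCU_CODONS))
        virus = pd.DataFrame(data[5:], index=[f"v{i}" for i in range(3)], columns=list(RSCU_CODONS))
        proj = rscu_pca(host, virus)
        assert proj.variance_explained[0] == pytest.approx(1.0, abs=1e-9)
        assert proj.variance_explained[1] == pytest.approx(0.0, abs=1e-9)

    def test_variance_explained_non_increasing_and_bounded(self):
        rng = np.random.default_rng(3)
        proj = rscu_pca(random_rscu_frame(rng, 10, "h"), random_rscu_frame(rng, 4, "v"))
        v = proj.variance_explained
        assert all(a >= b - 1e-12 for a, b in zip(v, v[1:]))
        assert all(0 <= x <= 1 for x in v)
        assert sum(v) == pytest.approx(1.0)
        assert len(v) >= 4

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        host = random_rscu_frame(rng, 6, "h")
        virus = random_rscu_frame(rng, 2, "v")
        proj = rscu_pca(host, virus)
        for col in proj.loadings.columns:
            load = proj.loadings[col].to_numpy()
            assert load[np.argmax(np.abs(load))] > 0

    def test_too_few_rows_raises(self):
        rng = np.random.default_rng(5)
        host = random_rscu_frame(rng, 1, "h")
        with pytest.raises(ValueError):
            rscu_pca(host.iloc[:0], host)

    def test_joint_differs_from_host_only(self):
        rng = np.random.default_rng(6)
        host = random_rscu_frame(rng, 10, "h")
        virus = random_rscu_frame(rng, 5, "v") + 1.0  # shifted cloud
        joint = rscu_pca(host, virus)
        host_only = rscu_pca(host.iloc[:5], host.iloc[5:])
        joint_host_scores = joint.scores.loc[host.index, "pc1"].to_numpy()
        host_only_scores = host_only.scores.loc[host.index, "pc1"].to_numpy()
        assert not np.allclose(np.abs(joint_host_scores), np.abs(host_only_scores))


class TestCircles:
    def test_single_virus(self):
        proj = manual_projection(
            pd.DataFrame({"pc1": [1.0], "pc2": [2.0]}, index=["v0"]), ["v0"]
        )
        circle = cluster_circle(proj, ["v0"])
        assert circle.center == (1.0, 2.0)
        assert circle.radius == 0.0

    def test_two_viruses_symmetry(self):
        scores = pd.DataFrame({"pc1": [0.0, 0.0], "pc2": [0.0, 2.0]}, index=["v0", "v1"])
        proj = manual_projection(scores, ["v0", "v1"])
        circle = cluster_circle(proj, ["v0", "v1"])
        assert circle.center == (0.0, 1.0)
        assert circle.radius == pytest.approx(1.0)

    def test_brute_force_radius(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-3, 3, size=(6, 2))
        ids = [f"v{i}" for i in range(6)]
        proj = manual_projection(pd.DataFrame(pts, index=ids, columns=["pc1", "pc2"]), ids)
        circle = cluster_circle(proj, ids)
        center = pts.mean(axis=0)
        ref = max(np.hypot(*(p - center)) for p in pts)
        assert circle.radius == pytest.approx(ref, abs=1e-12)
        # every member within the radius
        for p in pts:
            assert np.hypot(*(p - center)) <= circle.radius + 1e-12

    def test_unknown_id_raises(self):
        scores = pd.DataFrame({"pc1": [0.0], "pc2": [0.0]}, index=["v0"])
        proj = manual_projection(scores, ["v0"])
        with pytest.raises(KeyError):
            cluster_circle(proj, ["nope"])


class TestSelection:
    def _proj(self):
        scores = pd.DataFrame(
            {
                "pc1": [0.0, 0.05, 0.1, 0.29, 0.31, 5.0],
                "pc2": [0.0, 0.0, 0.0, 0.0, 0.0, 5.0],
            },
            index=["v0", "g_at_005", "g_at_01", "g_at_029", "g_at_031", "g_far"],
        )
        return manual_projection(scores, ["v0"])

    def test_radius_zero_selects_nothing_generic(self):
        sel = per_virus_circle(self._proj(), "v0", radius=0.0)
        assert sel.selected_gene_ids == ()

    def test_distance_thresholds(self):
        sel = per_virus_circle(self._proj(), "v0", radius=0.3)
        assert set(sel.selected_gene_ids) == {"g_at_005", "g_at_01", "g_at_029"}

    def test_monotone_in_radius(self):
        proj = self._proj()
        previous: set = set()
        for r in (0.0, 0.05, 0.1, 0.3, 10.0):
            current = set(per_virus_circle(proj, "v0", radius=r).selected_gene_ids)
            assert previous <= current
            previous = current

    def test_full_range_circle_selects_all_hosts(self):
        proj = self._proj()
        sel = per_virus_circle(proj, "v0", radius=100.0)
        assert set(sel.selected_gene_ids) == set(proj.host_ids)

    def test_viruses_never_selected(self):
        sel = per_virus_circle(self._proj(), "v0", radius=100.0)
        assert "v0" not in sel.selected_gene_ids

    def test_boundary_is_inclusive(self):
        proj = self._proj()
        circle = SelectionCircle(center=(0.0, 0.0), radius=0.29, member_virus_ids=("v0",))
        sel = select_similar_genes(proj, circle)
        assert "g_at_029" in sel.selected_gene_ids

    def test_membership_invariant_under_sign_flip(self):
        proj = self._proj()
        circle = cluster_circle(proj, ["v0"])
        flipped_scores = proj.scores * -1.0
        flipped = PcaProjection(
            scores=flipped_scores,
            variance_explained=proj.variance_explained,
            loadings=proj.loadings,
            virus_ids=proj.virus_ids,
            host_ids=proj.host_ids,
        )
        flipped_circle = SelectionCircle(
            center=(-circle.center[0], -circle.center[1]),
            radius=circle.radius,
            member_virus_ids=circle.member_virus_ids,
        )
        a = select_similar_genes(proj, SelectionCircle(circle.center, 0.3, ("v0",)))
        b = select_similar_genes(flipped, SelectionCircle(flipped_circle.center, 0.3, ("v0",)))
        assert set(a.selected_gene_ids) == set(b.selected_gene_ids)

    def test_unknown_virus_raises(self):
        with pytest.raises(KeyError):
            per_virus_circle(self._proj(), "missing")


class TestMissingTrnaReport:
    def _vec(self, values):
        from cubkit.cub_metrics import CodonCountTable, rscu

        return rscu(CodonCountTable.from_counts(values))

    def test_no_zero_copy_codons_empty(self):
        vec = self._vec({"TTT": 2, "TTC": 2})
        table = missing_trna_codon_report({"s1": vec}, {"TTT": 3, "TTC": 1})
        assert table.empty

    def test_exclusive_use_flagged(self):
        vec = self._vec({"TTT": 10})  # Phe entirely on TTT -> RSCU 2.0
        table = missing_trna_codon_report({"s1": vec}, {"TTT": 0, "TTC": 5})
        assert len(table) == 1
        row = table.iloc[0]
        assert row["codon"] == "TTT"
        assert row["rscu"] == pytest.approx(2.0)
        assert bool(row["over_represented"])

    def test_planted_bias_flags_only_biased_virus(self):
        biased = self._vec({"CTG": 20, "GGG": 20})  # Leu on CTG, Gly on GGG
        balanced = self._vec(
            {"CTG": 2, "CTT": 2, "CTA": 2, "CTC": 2, "TTA": 2, "TTG": 2,
             "GGG": 2, "GGA": 2, "GGT": 2, "GGC": 2}
        )
        trna = {"CTG": 0, "GGG": 0, "CTT": 4}
        table = missing_trna_codon_report({"biased": biased, "ok": balanced}, trna)
        flagged = table[table["over_represented"]]
        assert set(flagged["id"]) == {"biased"}
        assert set(flagged["codon"]) == {"CTG", "GGG"}

    def test_read_trna_table(self, tmp_path):
        path = tmp_path / "trna.tsv"
        path.write_text("codon\tcopy_number\nttt\t3\nGGG\t0\n")
        assert read_trna_table(path) == {"TTT": 3, "GGG": 0}
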