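"""Profile clustering and the characterization battery."""

import numpy as np
import pandas as pd
import pytest

import dosegrade as dg
from dosegrade import cluster as cl

from conftest import tiny_design


def _profiles_from(matrix):
    return pd.DataFrame(matrix, index=[f"g{i}" for i in range(len(matrix))])


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("values,pc,expected", [
    ([1.0, 1.0, 1.0], 1.0, 1.0),        # log2(2)
    ([0.0, 0.0, 0.0], 1.0, 0.0),
    ([1.0, 3.0], 1.0, 1.5),             # mean of log2(2), log2(4)
])
def test_profile_matrix_replicate_mean_after_log(values, pc, expected):
    design = tiny_design(("WT",), (0.0,), len(values))
    rpkm = pd.DataFrame([values], index=["g1"], columns=design["sample_id"])
    prof = cl.build_profile_matrix(rpkm, design, ["g1"], pseudocount=pc)
    assert prof.loc["g1", ("WT", 0.0)] == pytest.approx(expected)


def test_profile_matrix_missing_gene_errors(small_data, small_de):
    lengths = small_data.truth.set_index("gene_id")["length_bp"]
    rpkm = dg.compute_rpkm(small_data.counts, lengths)
    with pytest.raises(KeyError):
        cl.build_profile_matrix(rpkm, small_data.design, ["NOT_A_GENE"])


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_two_blobs_recovered_exactly(rng):
    a = rng.normal(0.0, 1.0, size=(20, 21))
    b = rng.normal(20.0, 1.0, size=(20, 21))
    prof = _profiles_from(np.vstack([a, b]))
    labels, _ = cl.hierarchical_cluster(prof, k=2)
    first, second = set(labels.iloc[:20]), set(labels.iloc[20:])
    assert len(first) == len(second) == 1 and first != second


def test_k_equals_n_gives_singletons(rng):
    prof = _profiles_from(rng.normal(size=(8, 5)))
    labels, _ = cl.hierarchical_cluster(prof, k=8)
    assert labels.nunique() == 8


def test_duplicated_rows_co_cluster(rng):
    m = rng.normal(size=(10, 6))
    m[7] = m[2]
    labels, _ = cl.hierarchical_cluster(_profiles_from(m), k=5)
    assert labels.iloc[7] == labels.iloc[2]


def test_k_larger_than_n_errors(rng):
    with pytest.raises(ValueError):
        cl.hierarchical_cluster(_profiles_from(rng.normal(size=(3, 4))), k=5)


def test_partition_stable_under_row_shuffle(rng):
    prof = _profiles_from(rng.normal(size=(40, 21)))
    labels1, _ = cl.hierarchical_cluster(prof, k=6)
    perm = rng.permutation(prof.index)
    labels2, _ = cl.hierarchical_cluster(prof.loc[perm], k=6)

    def partition(lab):
        return frozenset(frozenset(lab.index[lab == v]) for v in lab.unique())

    assert partition(labels1) == partition(labels2)


# ---------------------------------------------------------------------------
# direction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("lo,hi,expected", [
    (1.0, 5.0, "up"),
    (5.0, 1.0, "down"),
    (2.0, 2.0, "unchanged"),
])
def test_classify_direction(lo, hi, expected):
    design = tiny_design(("WT",), (0.0, 1000.0), 2)
    rpkm = pd.DataFrame([[lo, lo, hi, hi]], index=["g1"],
                        columns=design["sample_id"])
    assert cl.classify_direction(rpkm, design).loc["g1"] == expected


# ---------------------------------------------------------------------------
# resampling and categorical tests
# ---------------------------------------------------------------------------

def test_resampling_extreme_cluster_gets_minimal_p(rng):
    obs, p, direction = cl.resampling_median_test(
        np.full(10, 100.0), np.full(100, 1000.0), B=1000, rng=rng)
    assert p == pytest.approx(2.0 / 1001.0)
    assert direction == "less"


def test_resampling_reproducible_and_background_check():
    a = cl.resampling_median_test([1, 2, 3], np.arange(50), B=200,
                                  rng=np.random.default_rng(5))
    b = cl.resampling_median_test([1, 2, 3], np.arange(50), B=200,
                                  rng=np.random.default_rng(5))
    assert a == b
    with pytest.raises(ValueError):
        cl.resampling_median_test(np.arange(10), np.arange(5), B=10)


def test_categorical_enrichment():
    # matched fractions: no signal
    _, p, _ = cl.categorical_enrichment_test([True] * 5 + [False] * 5,
                                             [True] * 50 + [False] * 50)
    assert p > 0.5
    # extreme enrichment
    d, p, _ = cl.categorical_enrichment_test(
        [True] * 25 + [False] * 25, [True] * 5 + [False] * 995)
    assert d == "over" and p < 1e-6
    # attribute absent everywhere: degenerate, p = 1
    _, p, method = cl.categorical_enrichment_test([False] * 10, [False] * 100)
    assert p == 1.0


def test_cluster_table_statistics(rng):
    """Planted short TSS-E-box distances are flagged; percentages and sizes
    are internally consistent."""
    n_cl, n_bg = 30, 300
    design = tiny_design(("WT", "T58A", "T58I"), (0.0, 1000.0), 2)
    genes = [f"g{i}" for i in range(n_cl + n_bg)]
    base = rng.uniform(1, 10, size=(len(genes), 1))
    slope = np.ones(len(genes))
    slope[:n_cl] = 3.0  # cluster genes go up
    vals = base * np.where(np.tile(design["dose"].to_numpy(), (len(genes), 1)) > 0,
                           slope[:, None], 1.0)
    rpkm = pd.DataFrame(vals, index=genes, columns=design["sample_id"])
    ann = pd.DataFrame({
        "gene_id": genes,
        "biotype": rng.choice(["protein_coding", "non_coding"], len(genes)),
        "length_bp": rng.integers(500, 5000, len(genes)),
    })
    dist = pd.DataFrame({
        "gene_id": genes,
        "min_distance": np.r_[rng.integers(50, 150, n_cl),
                              rng.integers(4000, 6000, n_bg)].astype(float),
    })
    dist["ebox_within_1kb"] = dist["min_distance"] <= 1000
    assignments = pd.Series(np.r_[np.ones(n_cl, int),
                                  np.full(20, 2, int)],
                            index=genes[:n_cl + 20])
    table = cl.build_cluster_table(assignments, rpkm, design, ann, dist,
                                   background_genes=genes[n_cl + 20:],
                                   B=500, rng=rng)
    assert table["n_genes"].sum() == len(assignments)
    row = table.loc[1]
    assert row["pct_up"] == 100.0 and row["overall_pattern"] == "up"
    assert row["pct_up"] + row["pct_down"] + row["pct_unchanged"] == pytest.approx(100.0)
    assert row["tss_ebox_direction"] == "less"
    assert row["tss_ebox_padj"] < 0.02
    assert row["ebox_direction"] == "over" and row["ebox_padj"] < 0.05


def test_single_cluster_adjusted_equals_raw(rng):
    design = tiny_design(("WT",), (0.0, 1000.0), 2)
    genes = [f"g{i}" for i in range(60)]
    rpkm = pd.DataFrame(rng.uniform(1, 5, size=(60, len(design))),
                        index=genes, columns=design["sample_id"])
    ann = pd.DataFrame({"gene_id": genes, "biotype": "protein_coding",
                        "length_bp": 1000})
    dist = pd.DataFrame({"gene_id": genes,
                         "min_distance": rng.integers(0, 3000, 60).astype(float)})
    dist["ebox_within_1kb"] = dist["min_distance"] <= 1000
    assignments = pd.Series(1, index=genes[:20])
    table = cl.build_cluster_table(assignments, rpkm, design, ann, dist,
                                   background_genes=genes[20:], B=200, rng=rng)
    assert table.loc[1, "length_padj"] == pytest.approx(table.loc[1, "length_p"])


def test_newick_roundtrip_leaf_names(rng):
    prof = _profiles_from(rng.normal(size=(6, 4)))
    _, Z = cl.hierarchical_cluster(prof, k=2)
    nwk = cl.dendrogram_newick(Z, prof.index)
    assert nwk.endswith(";")
    for name in prof.index:
        assert name in nwk
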