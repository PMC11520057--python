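"""Aggregation, BH adjustment, retention lines and the final call table."""

from itertools import permutations

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from emptydropsmultiome import (
    AmbientProfile,
    LibrarySizeModel,
    ModalityPValues,
    MultiomeCounts,
    ValidationError,
    aggregate_pvalues,
    bh_adjust,
    call_cells,
    fit_retention_lines,
)
from helpers import bh_oracle


def test_aggregate_pvalue_rules():
    assert aggregate_pvalues(0.02, 0.04) == pytest.approx(0.03)
    # absent modality counts as p = 1 before averaging
    assert aggregate_pvalues(0.5, None) == pytest.approx(0.75)
    assert aggregate_pvalues(None, 0.5) == pytest.approx(0.75)
    # validity-guaranteed rule doubles the mean, capped at 1
    assert aggregate_pvalues(1.0, 1.0, multiplier=2.0) == 1.0
    assert aggregate_pvalues(0.01, 0.03, multiplier=2.0) == pytest.approx(0.04)
    with pytest.raises(ValidationError):
        aggregate_pvalues(None, None)
    with pytest.raises(ValidationError):
        aggregate_pvalues(0.0, 0.5)


def test_bh_matches_hand_oracle():
    assert bh_adjust(np.array([0.01, 0.02, 0.03, 1.0])) == pytest.approx(
        [0.04, 0.04, 0.04, 1.0]
    )
    assert bh_adjust(np.array([1.0, 1.0])) == pytest.approx([1.0, 1.0])
    assert bh_adjust(np.array([0.37])) == pytest.approx([0.37])
    with pytest.raises(ValidationError):
        bh_adjust(np.array([0.5, 1.5]))
    with pytest.raises(ValidationError):
        bh_adjust(np.array([]))


def test_bh_on_all_permutations_of_four_pvalues():
    base = [0.01, 0.2, 0.5, 1.0]
    for perm in permutations(base):
        assert bh_adjust(np.array(perm)) == pytest.approx(bh_oracle(list(perm)))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=25))
def test_bh_oracle_equivalence_property(pvals):
    assert bh_adjust(np.array(pvals)) == pytest.approx(bh_oracle(pvals))


def _models(b_a=5.0, l_a=300.0, b_r=5.0, l_r=300.0):
    def make(modality, b, l):
        return LibrarySizeModel(
            modality=modality,
            weights=np.full(3, 1 / 3),
            means=np.array([0.0, 1.8, 3.5]),
            sds=np.array([0.1, 0.2, 0.2]),
            b=b,
            l=l,
        )

    return make("ATAC", b_a, l_a), make("RNA", b_r, l_r)


def _two_blob_totals(seed=0, n=400):
    rng = np.random.default_rng(seed)
    low = 10 ** rng.normal([2.0, 1.5], 0.1, size=(n, 2))
    high = 10 ** rng.normal([4.0, 3.5], 0.1, size=(n, 2))
    pts = np.vstack([low, high])
    return pts[:, 0], pts[:, 1]


def test_retention_lines_bisect_centroids():
    t_a, t_r = _two_blob_totals()
    model_a, model_r = _models()
    lines = fit_retention_lines(t_a, t_r, (model_a, model_r), seed=0)
    d = [
        lines.signed_offset(c[0], c[1]) - lines.kmeans_offset
        for c in lines.centroids
    ]
    # centroids are equidistant from the line, on opposite sides
    assert d[0] == pytest.approx(-d[1], rel=1e-6)
    assert d[0] < 0 < d[1]


def test_lower_line_passes_through_ambient_anchor():
    t_a, t_r = _two_blob_totals(1)
    model_a, model_r = _models(l_a=250.0, l_r=120.0)
    lines = fit_retention_lines(t_a, t_r, (model_a, model_r), seed=1)
    x = np.log10(250.0)
    y_on_line = lines.slope * x + lines.lower_intercept
    assert y_on_line == pytest.approx(np.log10(120.0), abs=1e-9)


def test_upper_line_above_kmeans_line():
    t_a, t_r = _two_blob_totals(2)
    lines = fit_retention_lines(t_a, t_r, _models(), seed=2)
    assert lines.upper_offset >= lines.kmeans_offset


def _call_table_fixture(p_rna, p_atac, t_a, t_r, **kwargs):
    n = len(t_a)
    mc = MultiomeCounts(
        rna_counts=sp.csc_matrix(np.vstack([np.asarray(t_r), np.zeros(n, dtype=int)])),
        atac_counts=sp.csc_matrix(np.vstack([np.asarray(t_a), np.zeros(n, dtype=int)])),
        barcodes=np.array([f"B{i}" for i in range(n)], dtype=object),
        gene_ids=np.array(["g0", "g1"], dtype=object),
        region_ids=np.array(["r0", "r1"], dtype=object),
    )
    model_a, model_r = _models(**kwargs)

    def pv(modality, values, b_key):
        values = np.asarray(values, dtype=float)
        tested = ~np.isnan(values)
        m_c = np.where(tested, 10, -1)
        return ModalityPValues(modality, tested, values, m_c, n_iters=100)

    prof = AmbientProfile(
        modality="RNA",
        raw_counts=np.zeros(2, dtype=np.int64),
        proportions=np.array([0.5, 0.5]),
        n_soup_droplets=5,
        alpha=10.0,
    )
    return mc, (prof, prof), (model_a, model_r), pv("RNA", p_rna, "b"), pv("ATAC", p_atac, "b")


def test_call_cells_overrides_and_universe():
    # barcodes: 0 ambient-small (below lower line), 1 mid cell, 2 huge cell,
    # 3 untested in both modalities (technical)
    t_a = np.array([50, 5000, 80000, 1])
    t_r = np.array([40, 4000, 60000, 1])
    p_rna = [0.001, 0.0005, 0.9, np.nan]
    p_atac = [0.001, 0.0005, 0.9, np.nan]
    mc, profiles, models, pv_r, pv_a = _call_table_fixture(p_rna, p_atac, t_a, t_r)
    # a clearly separable blob pair for the k-means line
    table = call_cells(
        mc, profiles, models, pv_r, pv_a, fdr_threshold=0.01, retain_large=False
    )
    # technical barcode is not part of the tested universe
    assert "B3" not in set(table["barcode"])
    row0 = table.set_index("barcode").loc["B0"]
    assert bool(row0["below_lower"])
    assert row0["FDR"] == 1.0
    assert not bool(row0["is_cell"])  # overridden despite small p

    # retain_large rescues the huge soup-like barcode
    table2 = call_cells(
        mc, profiles, models, pv_r, pv_a, fdr_threshold=0.01, retain_large=True
    )
    row2 = table2.set_index("barcode").loc["B2"]
    assert bool(row2["above_upper"])
    assert row2["FDR"] == 0.0 and bool(row2["is_cell"])
    # without retain_large the same barcode is not called (soup-like p)
    assert not bool(table.set_index("barcode").loc["B2"]["is_cell"])


def test_call_threshold_monotonicity_and_limits():
    rng = np.random.default_rng(11)
    n = 60
    t_a = np.concatenate([10 ** rng.normal(2.0, 0.1, n), 10 ** rng.normal(4.0, 0.1, n)]).astype(int)
    t_r = np.concatenate([10 ** rng.normal(1.8, 0.1, n), 10 ** rng.normal(3.6, 0.1, n)]).astype(int)
    p = rng.uniform(0.001, 1.0, 2 * n)
    mc, profiles, models, pv_r, pv_a = _call_table_fixture(p, p, t_a, t_r)
    called_sets = []
    for thr in (0.5, 0.1, 0.01):
        table = call_cells(mc, profiles, models, pv_r, pv_a, fdr_threshold=thr)
        called_sets.append(set(table.loc[table["is_cell"], "barcode"]))
    assert called_sets[2] <= called_sets[1] <= called_sets[0]
    # threshold 1.0: every tested barcode not below the lower line is called
    table = call_cells(mc, profiles, models, pv_r, pv_a, fdr_threshold=1.0)
    assert (table["is_cell"] == ~table["below_lower"]).all()


def test_retain_large_ablation():
    rng = np.random.default_rng(12)
    n = 50
    t_a = np.concatenate([10 ** rng.normal(2.0, 0.1, n), 10 ** rng.normal(4.0, 0.1, n)]).astype(int)
    t_r = np.concatenate([10 ** rng.normal(1.8, 0.1, n), 10 ** rng.normal(3.6, 0.1, n)]).astype(int)
    p = rng.uniform(0.001, 1.0, 2 * n)
    mc, profiles, models, pv_r, pv_a = _call_table_fixture(p, p, t_a, t_r)
    off = call_cells(mc, profiles, models, pv_r, pv_a, fdr_threshold=0.05)
    # with retain_large disabled the call depends only on FDR and the lower flag
    expect = (off["FDR"] <= 0.05) & ~off["below_lower"]
    assert (off["is_cell"] == expect).all()
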