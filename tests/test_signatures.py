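"""Signature derivation: discretization, Edgington combination, hierarchy."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from rnage import (
    DatasetPanelConfig,
    DETable,
    ValidationError,
    assign_signature_class,
    combine_pvalues_edgington,
    derive_signatures,
    discretize_lfc,
    irwin_hall_cdf,
    write_signatures,
)

# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "lfc,expected",
    [
        (0.05, 0),
        (-0.05, 0),
        (0.1, 1),       # boundary falls in the nonzero bin
        (-0.1, -1),
        (0.0, 0),
        (2.5, 1),
        (-0.3, -1),
    ],
)
def test_discretize_threeway(lfc, expected):
    assert discretize_lfc(lfc, 0.1) == expected


def test_discretize_vectorized_and_errors():
    np.testing.assert_array_equal(
        discretize_lfc([0.2, -0.2, 0.0], 0.1), [1, -1, 0]
    )
    with pytest.raises(ValidationError):
        discretize_lfc(float("nan"), 0.1)
    with pytest.raises(ValidationError):
        discretize_lfc(0.5, 0.0)


# ---------------------------------------------------------------------------
# Edgington / Irwin–Hall
# ---------------------------------------------------------------------------

def test_single_pvalue_passes_through():
    assert combine_pvalues_edgington([0.05]) == pytest.approx(0.05, abs=1e-15)


def test_symmetric_vectors_give_half():
    # sum of K uniforms is symmetric about K/2
    assert combine_pvalues_edgington([0.5] * 6) == pytest.approx(0.5, abs=1e-12)
    # K=2, s=1: closed form s^2/2 = 0.5
    assert combine_pvalues_edgington([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)


def test_edgington_input_validation():
    with pytest.raises(ValidationError):
        combine_pvalues_edgington([])
    with pytest.raises(ValidationError):
        combine_pvalues_edgington([0.5, 1.2])
    with pytest.raises(ValidationError):
        combine_pvalues_edgington([-0.1])


def test_zero_pvalues_allowed():
    # the sum-based method needs no pseudo-count
    assert combine_pvalues_edgington([0.0, 0.0, 0.0]) == 0.0


@pytest.mark.parametrize("k", range(1, 7))
def test_irwin_hall_matches_scipy(k, rng):
    """Closed form vs scipy's Irwin–Hall distribution on random points."""
    s = rng.uniform(0, k, size=200)
    expected = scipy.stats.irwinhall.cdf(s, k)
    np.testing.assert_allclose(irwin_hall_cdf(s, k), expected, atol=1e-12)


def test_edgington_matches_monte_carlo(rng):
    """Closed form agrees with a simulated uniform-sum CDF (small version)."""
    n_draws = 200_000
    for k in (2, 4, 6):
        sums = np.sort(rng.uniform(size=(n_draws, k)).sum(axis=1))
        pvecs = rng.uniform(size=(50, k))
        for p in pvecs:
            closed = combine_pvalues_edgington(p)
            mc = np.searchsorted(sums, p.sum(), side="right") / n_draws
            se = math.sqrt(max(closed * (1 - closed), 1e-12) / n_draws)
            assert abs(closed - mc) <= 3 * se + 3 / n_draws


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=6),
    p_small=st.floats(0, 1, allow_nan=False),
    p_big=st.floats(0, 1, allow_nan=False),
)
def test_edgington_monotone_in_added_pvalue(ps, p_small, p_big):
    """Appending a smaller p-value never yields a larger combined p."""
    lo, hi = sorted([p_small, p_big])
    assert combine_pvalues_edgington(ps + [lo]) <= combine_pvalues_edgington(ps + [hi]) + 1e-12


# ---------------------------------------------------------------------------
# hierarchical class assignment
# ---------------------------------------------------------------------------

def brute_force_class(v):
    """Independent re-statement of the hierarchy on the default panel order
    (Total_pF, PolyA_pF, PolyA_Gage_pF, Total_FC, PolyA_Gage_FC, Total_SN)."""
    if abs(v[0] + v[1] + v[2] + v[3] + v[4] + v[5]) == 6:
        return "Pan"
    if abs(v[0] + v[1] + v[2]) == 3:
        return "pF"
    if abs(v[3] + v[4] + v[5]) == 3:
        return "Neuronal"
    if abs(v[3] + v[4]) == 2:
        return "FC"
    if v[5] != 0:
        return "SN"
    return None


@pytest.mark.parametrize(
    "lbar,expected",
    [
        ((1, 1, 1, 1, 1, 1), "Pan"),
        ((-1,) * 6, "Pan"),
        ((1, 1, 1, 0, -1, 1), "pF"),
        ((0, 0, 0, 1, 1, -1), "FC"),
        ((0, 0, 0, 0, 0, -1), "SN"),
        ((0, 0, 0, 1, 1, 1), "Neuronal"),
        ((0, 0, 0, 0, 0, 0), None),
    ],
)
def test_assignment_examples(lbar, expected):
    assert assign_signature_class(lbar, DatasetPanelConfig()) == expected


def test_assignment_matches_brute_force_on_all_729_vectors():
    panel = DatasetPanelConfig()
    for v in itertools.product((-1, 0, 1), repeat=6):
        assert assign_signature_class(v, panel) == brute_force_class(v), v


def test_assignment_length_mismatch():
    with pytest.raises(ValidationError):
        assign_signature_class([1, 1, 1], DatasetPanelConfig())


# ---------------------------------------------------------------------------
# derivation
# ---------------------------------------------------------------------------

def _tables_from_arrays(panel, genes, lfc, pvals):
    tables = []
    for j, d in enumerate(panel.dataset_ids):
        tables.append(
            DETable(d, pd.DataFrame({"gene": genes, "log2fc": lfc[:, j], "pvalue": pvals[:, j]}))
        )
    return tables


def test_planted_concordant_genes_form_the_pan_signature(rng):
    """30 genes concordant in all six tables among 1000 nulls are exactly
    the Pan signature, with directions matching the planted signs."""
    panel = DatasetPanelConfig()
    n, n_planted = 1030, 30
    genes = [f"g{i:04d}" for i in range(n)]
    signs = np.where(rng.random(n_planted) < 0.5, 1.0, -1.0)
    lfc = np.zeros((n, 6))
    pvals = rng.uniform(size=(n, 6))
    lfc[:n_planted, :] = signs[:, None]  # |log2FC| = 1 everywhere
    pvals[:n_planted, :] = 1e-6
    sigs, audit = derive_signatures(_tables_from_arrays(panel, genes, lfc, pvals), panel)
    pan = sigs[0]
    assert pan.class_label == "Pan"
    assert sorted(pan.genes) == genes[:n_planted]
    by_gene = dict(zip(pan.genes, pan.directions))
    for g, s in zip(genes[:n_planted], signs):
        assert by_gene[g] == int(s)


def test_brute_force_re_derivation_small(rng):
    """Full derivation matches an independent per-gene re-derivation
    (scipy Irwin–Hall + explicit hierarchy + explicit ranking)."""
    panel = DatasetPanelConfig(top_n=5)
    n = 60
    genes = [f"g{i:03d}" for i in range(n)]
    lfc = rng.normal(0, 0.3, size=(n, 6))
    pvals = rng.uniform(size=(n, 6))
    sigs, audit = derive_signatures(_tables_from_arrays(panel, genes, lfc, pvals), panel)

    # oracle: per-gene loop written independently of the implementation
    subset_cols = {"Pan": range(6), "pF": range(3), "Neuronal": range(3, 6),
                   "FC": range(3, 5), "SN": range(5, 6)}
    records = {}
    for i, g in enumerate(genes):
        v = [0 if abs(x) < 0.1 else int(np.sign(x)) for x in lfc[i]]
        cls = brute_force_class(v)
        cp = float(scipy.stats.irwinhall.cdf(pvals[i].sum(), 6))
        records[g] = (cls, cp, v)
    for sig in sigs:
        cols = list(subset_cols[sig.class_label])
        eligible = [
            (records[g][1], -np.mean(np.abs(lfc[i, cols])), g)
            for i, g in enumerate(genes)
            if records[g][0] == sig.class_label
        ]
        expected = [g for _, _, g in sorted(eligible)[: panel.top_n]]
        assert sig.genes == expected
        for g in sig.genes:
            cls, cp, v = records[g]
            assert cp == pytest.approx(
                float(sig.entries.set_index("gene").loc[g, "combined_p"]), rel=1e-9
            )
            assert int(np.sign(sum(v[c] for c in cols))) == int(
                sig.entries.set_index("gene").loc[g, "direction"]
            )


def test_tissue_restricted_gene_lands_in_its_class_only(rng):
    panel = DatasetPanelConfig()
    n = 100
    genes = [f"g{i:03d}" for i in range(n)]
    lfc = np.zeros((n, 6))
    pvals = rng.uniform(size=(n, 6))
    # one gene significant only in the three fibroblast tables
    lfc[0, :3] = 1.0
    pvals[0, :3] = 1e-8
    sigs, _ = derive_signatures(_tables_from_arrays(panel, genes, lfc, pvals), panel)
    by_label = {s.class_label: s.genes for s in sigs}
    assert "g000" in by_label["pF"]
    for label in ("Pan", "Neuronal", "FC", "SN"):
        assert "g000" not in by_label[label]


def test_truncation_cannot_invent_genes(rng):
    """top_n larger than the eligible pool keeps the pool size."""
    panel = DatasetPanelConfig(top_n=100)
    n = 50
    genes = [f"g{i:03d}" for i in range(n)]
    lfc = np.zeros((n, 6))
    pvals = rng.uniform(size=(n, 6))
    lfc[:7, 3:5] = 1.0  # seven FC-only genes
    sigs, _ = derive_signatures(_tables_from_arrays(panel, genes, lfc, pvals), panel)
    fc = next(s for s in sigs if s.class_label == "FC")
    assert len(fc) == 7


def test_empty_gene_universe_is_an_error(rng):
    panel = DatasetPanelConfig()
    tables = []
    for j, d in enumerate(panel.dataset_ids):
        tables.append(
            DETable(d, pd.DataFrame({"gene": [f"only_{d}"], "log2fc": [0.0], "pvalue": [0.5]}))
        )
    with pytest.raises(ValidationError, match="universe"):
        derive_signatures(tables, panel)


def test_mutual_exclusivity_and_determinism(small_training, small_panel, tmp_path):
    tables, _ = small_training
    sigs1, _ = derive_signatures(tables, small_panel)
    sigs2, _ = derive_signatures(tables, small_panel)
    seen = set()
    for s in sigs1:
        assert not (set(s.genes) & seen)
        seen |= set(s.genes)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_signatures(p1, sigs1)
    write_signatures(p2, sigs2)
    assert p1.read_bytes() == p2.read_bytes()
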