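import math

import numpy as np
import pytest

from astrotraj.enrichment import (
    ContingencyTable,
    HomologyMap,
    SignatureSet,
    chi_squared_2x2,
    fisher_exact_2x2,
    map_homologs,
    ora_gene_sets,
    overlap_fisher,
    read_gmt,
    read_signature_tsv,
    tf_enrichment,
)


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


# ---------------------------------------------------------------- tables


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 0, 0, 1)
    with pytest.raises(ValueError):
        ContingencyTable(0, 0, 0, 0)
    t = ContingencyTable(2, 0, 0, 3)
    assert t.odds_ratio == float("inf")
    assert np.isnan(ContingencyTable(0, 0, 5, 5).odds_ratio)


# ---------------------------------------------------------------- fisher


def test_fisher_balanced_table():
    res = fisher_exact_2x2(ContingencyTable(1, 1, 1, 1))
    assert res.p_value == pytest.approx(1.0)
    assert res.odds_ratio == pytest.approx(1.0)


def test_fisher_perfect_separation():
    res = fisher_exact_2x2(ContingencyTable(5, 0, 0, 5))
    assert res.p_value == pytest.approx(2 / 252)


def test_fisher_5xfad_overlap_table():
    """The published human/5xFAD overlap counts give an overwhelmingly
    significant enrichment with a large odds ratio."""
    res = fisher_exact_2x2(ContingencyTable(29, 195, 167, 16621))
    assert res.p_value < 1e-4
    assert res.odds_ratio == pytest.approx(29 * 16621 / (195 * 167), rel=1e-12)
    assert res.odds_ratio > 10


def test_fisher_matches_margin_enumeration(rng):
    for _ in range(150):
        cells = rng.integers(0, 16, size=4)
        if cells.sum() == 0 or cells.sum() > 60:
            continue
        table = ContingencyTable(*map(int, cells))
        assert fisher_exact_2x2(table).p_value == pytest.approx(
            fisher_enumeration_oracle(table), abs=1e-10
        )


# ------------------------------------------------------------ chi-squared


def test_chi_squared_balanced_and_closed_form():
    res = chi_squared_2x2(ContingencyTable(10, 10, 10, 10))
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1
    # closed form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on the published
    # transcription-factor table
    a, b, c, d = 17, 127, 1112, 15756
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    res = chi_squared_2x2(ContingencyTable(a, b, c, d))
    assert res.statistic == pytest.approx(expected, rel=1e-12)
    assert res.df == 1


def test_chi_squared_zero_margin_errors():
    with pytest.raises(ValueError, match="margin"):
        chi_squared_2x2(ContingencyTable(0, 0, 5, 5))


def test_chi_squared_yates_reduces_statistic():
    plain = chi_squared_2x2(ContingencyTable(12, 5, 3, 14))
    yates = chi_squared_2x2(ContingencyTable(12, 5, 3, 14), yates=True)
    assert yates.statistic < plain.statistic


# ---------------------------------------------------------------- overlap


def test_overlap_fisher_reproduces_published_cells():
    universe = [f"G{i}" for i in range(17012)]
    a = set(universe[:224])                      # mapped 5xFAD signature
    b = set(universe[:29]) | set(universe[300:467])  # 29 shared of 196
    res = overlap_fisher(a, b, universe)
    t = res.table
    assert (t.a, t.b, t.c, t.d) == (29, 195, 167, 16621)
    assert t.total == 17012


def test_overlap_fisher_identical_and_disjoint_sets():
    universe = {f"G{i}" for i in range(100)}
    same = {f"G{i}" for i in range(10)}
    res = overlap_fisher(same, same, universe)
    assert res.table.b == 0 and res.table.c == 0
    assert res.p_value < 1e-10
    other = {f"G{i}" for i in range(10, 20)}
    res2 = overlap_fisher(same, other, universe)
    assert res2.odds_ratio < 1 or res2.p_value > 0.9


def test_overlap_fisher_rejects_out_of_universe():
    with pytest.raises(ValueError, match="outside the universe"):
        overlap_fisher({"X"}, {"G1"}, {"G1", "G2"})


# --------------------------------------------------------------- homology


def test_map_homologs_toy():
    hmap = HomologyMap({"Gfap": "GFAP"})
    sig = SignatureSet("mouse", ["Gfap", "Xyz1"], {"Gfap": "up"})
    mapped, unmapped = map_homologs(sig, hmap, {"GFAP"})
    assert mapped.genes == ["GFAP"]
    assert mapped.directions == {"GFAP": "up"}
    assert unmapped == 1
    empty, miss = map_homologs(SignatureSet("m", []), hmap, {"GFAP"})
    assert empty.genes == [] and miss == 0
    with pytest.raises(ValueError, match="universe"):
        map_homologs(sig, hmap, set())


def test_map_homologs_reproduces_5xfad_mapping_counts():
    """A synthetic homology table built to the published outcome: 254
    mouse genes (239 up / 15 down) of which 224 (210 up / 14 down) map
    into the human universe."""
    up = [f"MUp{i}" for i in range(239)]
    down = [f"MDn{i}" for i in range(15)]
    sig = SignatureSet("dAA_5xFAD", up + down, {g: "up" for g in up} | {g: "down" for g in down})
    pairs = {g: g.upper() for g in up[:210] + down[:14]}
    universe = set(pairs.values()) | {f"H{i}" for i in range(500)}
    mapped, unmapped = map_homologs(sig, HomologyMap(pairs), universe)
    assert len(mapped.genes) == 224
    assert len(mapped.subset("up")) == 210
    assert len(mapped.subset("down")) == 14
    assert unmapped == 30


# --------------------------------------------------------------------- TF


def test_tf_enrichment_builds_published_tables():
    """Universe of 17,012 genes with 1129 TFs; signature of 196 with 18
    TFs (1/52 up, 17/144 down) yields the published 2x2 cells."""
    tfs = [f"TF{i}" for i in range(1129)]
    non = [f"G{i}" for i in range(17012 - 1129)]
    universe = set(tfs) | set(non)
    up = tfs[:1] + non[:51]
    down = tfs[1:18] + non[51:178]
    sig = SignatureSet(
        "dysregulated", up + down, {g: "up" for g in up} | {g: "down" for g in down}
    )
    results = tf_enrichment(sig, tfs, universe)
    t_down = results["down"].table
    assert (t_down.a, t_down.b, t_down.c, t_down.d) == (17, 127, 1112, 15756)
    t_all = results["all"].table
    assert (t_all.a, t_all.b) == (18, 178)
    assert results["down"].p_value < 0.05
    assert t_down.odds_ratio > 1


def test_tf_enrichment_error_paths():
    with pytest.raises(ValueError, match="empty signature"):
        tf_enrichment(SignatureSet("s", []), ["TF1"], {"TF1", "G1"})
    with pytest.raises(ValueError, match="transcription factors"):
        tf_enrichment(SignatureSet("s", ["G1"]), ["TFX"], {"G1", "G2"})


def test_tf_enrichment_all_tf_signature_has_or_above_one():
    universe = {f"TF{i}" for i in range(10)} | {f"G{i}" for i in range(10)}
    sig = SignatureSet("s", [f"TF{i}" for i in range(5)])
    res = tf_enrichment(sig, [f"TF{i}" for i in range(10)], universe)
    assert res["all"].table.odds_ratio > 1


# -------------------------------------------------------------------- ORA


def test_ora_orders_and_adjusts(rng):
    universe = {f"G{i}" for i in range(200)}
    sig = SignatureSet("s", [f"G{i}" for i in range(20)])
    collection = {
        "self": [f"G{i}" for i in range(20)],
        "half": [f"G{i}" for i in range(10)] + [f"G{i}" for i in range(100, 110)],
        "disjoint": [f"G{i}" for i in range(100, 130)],
    }
    table = ora_gene_sets(sig, collection, universe)
    assert table["set"].iloc[0] == "self"
    assert table.set_index("set").loc["disjoint", "p"] == pytest.approx(1.0)
    # q-values equal longhand step-up adjustment of the per-set p list
    p = table["p"].to_numpy()
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        prev = min(prev, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = prev
    assert np.allclose(table["q"], np.minimum(q, 1.0), atol=1e-12)
    with pytest.raises(ValueError):
        ora_gene_sets(sig, {}, universe)


# --------------------------------------------------------------------- IO


def test_gmt_and_signature_tsv_readers(tmp_path):
    gmt = tmp_path / "sets.gmt"
    gmt.write_text("setA\tdesc\tG1\tG2\nsetB\t-\tG3\n")
    collection = read_gmt(gmt)
    assert collection == {"setA": ["G1", "G2"], "setB": ["G3"]}
    bad = tmp_path / "bad.gmt"
    bad.write_text("only\ttwo\n")
    with pytest.raises(ValueError, match="GMT"):
        read_gmt(bad)
    sig_path = tmp_path / "sig.tsv"
    sig_path.write_text("gene\tdirection\nVIM\tup\nNRXN1\tdown\n")
    sig = read_signature_tsv(sig_path)
    assert sig.genes == ["VIM", "NRXN1"]
    assert sig.directions == {"VIM": "up", "NRXN1": "down"}


def test_signature_set_validation():
    with pytest.raises(ValueError, match="duplicate"):
        SignatureSet("s", ["A", "A"])
    with pytest.raises(ValueError, match="non-member"):
        SignatureSet("s", ["A"], {"B": "up"})
    with pytest.raises(ValueError, match="'up' or 'down'"):
        SignatureSet("s", ["A"], {"A": "sideways"})
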