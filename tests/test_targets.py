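import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srnagradient.seqio import reverse_complement, to_rna
from srnagradient.targets import (DuplexAlignment, TargetConfig, align_window,
                                  classify_pair, evaluate_energy, score_duplex,
                                  scan_transcripts)

states_strategy = st.lists(st.sampled_from(["WC", "GU", "MM", "GAP"]),
                           min_size=12, max_size=21)


def predicate_oracle(states, gu_in_runs=True):
    """Direct restatement of the six printed criteria (rules 1-5)."""
    w = {"WC": 0.0, "GU": 0.5, "MM": 1.0, "GAP": 1.0}
    score = sum(w[s] for s in states)
    member = [(s != "WC") if gu_in_runs else (s in ("MM", "GAP")) for s in states]
    no_triple = not any(member[i] and member[i + 1] and member[i + 2]
                        for i in range(len(states) - 2))
    no_adjacent_2_12 = not any(member[i] and member[i + 1] for i in range(1, 11))
    return {
        "score": score,
        "rule1": score <= 4,
        "rule2": no_triple,
        "rule3": no_adjacent_2_12,
        "rule4": states[9] == "WC" and states[10] == "WC",
        "rule5": sum(w[s] for s in states[:12]) <= 2.5,
    }


def test_perfect_duplex_passes_all_position_rules():
    v = score_duplex(["WC"] * 21)
    assert v.score == 0
    assert v.rule1 and v.rule2 and v.rule3 and v.rule4 and v.rule5


def test_mismatch_at_position_ten_fails_rule4_only():
    states = ["WC"] * 21
    states[9] = "MM"  # 1-based position 10
    v = score_duplex(states)
    assert not v.rule4
    assert v.rule1 and v.rule2 and v.rule3 and v.rule5


def test_nine_wobbles_in_tail_break_score_limit():
    states = ["WC"] * 12 + ["GU"] * 9  # positions 13-21
    v = score_duplex(states)
    assert v.score == 4.5
    assert not v.rule1
    assert v.rule5  # positions 1-12 are clean


def test_short_alignment_is_error():
    with pytest.raises(ValueError):
        score_duplex(["WC"] * 11)


@settings(derandomize=True, max_examples=300)
@given(states_strategy)
def test_rules_match_predicate_oracle(states):
    v = score_duplex(states)
    o = predicate_oracle(states)
    assert (v.score, v.rule1, v.rule2, v.rule3, v.rule4, v.rule5) == (
        o["score"], o["rule1"], o["rule2"], o["rule3"], o["rule4"], o["rule5"])


@settings(derandomize=True, max_examples=300)
@given(states_strategy)
def test_gu_switch_matches_oracle(states):
    v = score_duplex(states, gu_in_runs=False)
    o = predicate_oracle(states, gu_in_runs=False)
    assert (v.rule2, v.rule3) == (o["rule2"], o["rule3"])


@settings(derandomize=True, max_examples=200)
@given(states_strategy, st.integers(0, 20))
def test_score_monotone_under_degradation(states, pos):
    """WC -> GU and GU -> MM never decrease the mismatch score."""
    pos = pos % len(states)
    base = score_duplex(states).score
    for worse in ("GU", "MM"):
        degraded = list(states)
        if (worse == "GU" and degraded[pos] == "WC") or \
           (worse == "MM" and degraded[pos] in ("WC", "GU")):
            degraded[pos] = worse
            assert score_duplex(degraded).score >= base


def test_alignment_state_classification():
    assert classify_pair("A", "U") == "WC"
    assert classify_pair("G", "U") == "GU"
    assert classify_pair("U", "G") == "GU"
    assert classify_pair("A", "A") == "MM"


def test_duplex_alignment_invariants():
    with pytest.raises(ValueError):
        DuplexAlignment("ACGU", "ACGU", ("WC", "WC"))


MIR = "UGACAGAAGAGAGUGAGCACA"


def test_exact_complement_site_found_once():
    site = to_rna(reverse_complement(MIR.replace("U", "T")))
    transcript = "CGAUCGAUCG" * 5 + site + "GCUAGCUAGC" * 5
    hits = scan_transcripts("m1", MIR, {"t1": transcript})
    assert len(hits) == 1
    h = hits[0]
    assert h.verdict.score == 0 and h.verdict.all_pass
    assert (h.start, h.end) == (50, 71)
    assert h.verdict.mfe_ratio == pytest.approx(1.0)


def test_shuffled_transcripts_yield_no_hits():
    rng = np.random.default_rng(17)
    n_hits = 0
    for _ in range(100):
        transcript = "".join("ACGU"[i] for i in rng.integers(0, 4, 150))
        n_hits += len(scan_transcripts("m1", MIR, {"t": transcript}))
    assert n_hits == 0


def test_bulged_site_recovered_with_gap():
    site = to_rna(reverse_complement(MIR.replace("U", "T")))
    bulged = site[:3] + "A" + site[3:]  # one extra target nucleotide
    transcript = "GCGCGCGCGC" + bulged + "CGCGCGCGCG"
    hits = scan_transcripts("m1", MIR, {"t1": transcript})
    assert len(hits) == 1
    assert hits[0].verdict.score == 1.0
    assert "GAP" in hits[0].alignment.states
    assert not scan_transcripts("m1", MIR, {"t1": transcript},
                                TargetConfig(allow_gap=False))


def test_planted_graded_sites_exactly_recovered(sim_run, pipeline_report):
    """Only the pass-all planted sites may be reported, and all of them."""
    want = {(s["mirna"], t_id, s["start"], s["end"])
            for t_id, sites in sim_run.truth["target_sites"].items()
            for s in sites if s["label"] == "pass_all"}
    got = {(h.mirna_id, h.transcript_id, h.start, h.end)
           for h in pipeline_report.target_hits}
    assert got == want


def test_evaluate_energy_sets_rule6():
    site = to_rna(reverse_complement(MIR.replace("U", "T")))
    v = score_duplex(align_window(MIR, site, allow_gap=False))
    v = evaluate_energy(v, MIR, site)
    assert v.rule6 and v.mfe_ratio == pytest.approx(1.0)
    bad = "A" * len(MIR)
    v2 = score_duplex(["MM"] * len(MIR))
    v2 = evaluate_energy(v2, MIR, bad)
    assert not v2.rule6 and v2.mfe_ratio == 0.0
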