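"""Independent brute-force oracles used only by the test suite.

These never call the library's junction/consequence machinery: they build
the full mutant/skipped coding sequence, translate it end-to-end with
Biopython and derive the expected answer from the protein diff.
"""

from Bio.Seq import Seq


def translate(seq: str) -> str:
    pad = (-len(seq)) % 3
    return str(Seq(seq + "N" * pad).translate())


def oracle_skip_junction_event(model, exon_index: int) -> str:
    """Junction event of an in-frame exon skip, from full-CDS re-translation."""
    a, b = model.exon_cds_interval(exon_index)
    assert (b - a + 1) % 3 == 0, "oracle only defined for in-frame skips"
    cds = model.coding_sequence()
    skipped = cds[: a - 1] + cds[b:]
    p0 = translate(cds)
    p1 = translate(skipped)
    phase = (a - 1) % 3
    if phase == 0 or b == len(cds):
        expected = p0[: (a - 1) // 3] + p0[(a - 1) // 3 + (b - a + 1) // 3 :]
        assert p1 == expected, "codon-aligned skip must excise whole codons"
        return "none"
    i0 = (a - 1) // 3  # first (split) codon index
    fused_aa = p1[i0]
    up_aa = p0[i0]
    down_aa = p0[b // 3]
    # everything before and after the junction codon must be untouched
    n_removed = (b - a + 1) // 3
    assert p1[:i0] == p0[:i0]
    assert p1[i0 + 1 :] == p0[i0 + 1 + n_removed :]
    if fused_aa == "*":
        return "stop_gained"
    if fused_aa in (up_aa, down_aa):
        return "junction_synonymous"
    return "junction_missense"


def oracle_substitution_consequence(model, pos_c: int, alt: str) -> str:
    """Consequence of a CDS substitution by full re-translation."""
    cds = model.coding_sequence()
    mutant = cds[: pos_c - 1] + alt + cds[pos_c:]
    p0, p1 = translate(cds), translate(mutant)
    if p1 == p0:
        return "synonymous"
    s0, s1 = p0.find("*"), p1.find("*")
    if s1 >= 0 and (s0 < 0 or s1 < s0):
        return "nonsense"
    return "missense"
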