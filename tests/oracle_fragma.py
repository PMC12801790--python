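"""Independent brute-force oracle for the 21 end-motif features.

Pure-string enumeration over a small reference: no numpy, no shared code
with the package implementation. Used to cross-check the vectorized
extractor exactly on hand-built fixtures.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def _in_regions(chrom, pos, regions):
    return any(c == chrom and s <= pos < e for c, s, e in regions)


def enumerate_events(reference, fragments, regions, ends="both"):
    """[(chrom, pos, strand, motif)] for ends inside regions, N-free."""
    events = []
    for chrom, start, end in fragments:
        seq = reference[chrom]
        motif = seq[start : start + 3]
        if (
            len(motif) == 3
            and "N" not in motif
            and _in_regions(chrom, start, regions)
        ):
            events.append((chrom, start, "+", motif))
        if ends == "both" and end - 3 >= 0:
            motif = revcomp(seq[end - 3 : end])
            if len(motif) == 3 and "N" not in motif and _in_regions(chrom, end - 1, regions):
                events.append((chrom, end - 1, "-", motif))
    return events


def enumerate_fragma(reference, fragments, regions, ends="both"):
    """All 21 features by exhaustive enumeration; same zero-denominator
    pseudo-count convention as the package (denominator 1)."""
    events = enumerate_events(reference, fragments, regions, ends)
    total = len(events)
    feats = {}
    cgn_motifs = ["CGA", "CGC", "CGG", "CGT"]
    ncg_motifs = ["ACG", "CCG", "GCG", "TCG"]
    for m in cgn_motifs:
        feats[f"r_{m}"] = sum(1 for e in events if e[3] == m) / total if total else 0.0
    for m in ncg_motifs:
        feats[f"r_{m}"] = sum(1 for e in events if e[3] == m) / total if total else 0.0
    cgn = sum(1 for e in events if e[3] in cgn_motifs)
    ncg = sum(1 for e in events if e[3] in ncg_motifs)
    feats["r_CGN_over_NCG"] = cgn / ncg if ncg else float(cgn)

    # CGCG registers: map (chrom, pos, strand) -> counter name, first-come
    # in left-to-right occurrence order
    registers = {}
    for chrom, rs, re_ in regions:
        seq = reference[chrom]
        for p in range(rs, re_ - 3):
            if seq[p : p + 4] != "CGCG":
                continue
            up = seq[p - 1] if p >= 1 else "N"
            dn = seq[p + 4] if p + 4 < len(seq) else "N"
            plus = {}
            if up in "ACGT":
                plus[p - 1] = f"c_NCG_{up}"
            plus[p] = "c_CGC"
            plus[p + 1] = "c_GCG"
            if dn in "ACGT":
                plus[p + 2] = f"c_CGN_{dn}"
            minus = {}
            if dn in "ACGT":
                minus[p + 4] = f"c_NCG_{_COMP[dn]}"
            minus[p + 3] = "c_CGC"
            minus[p + 2] = "c_GCG"
            if up in "ACGT":
                minus[p + 1] = f"c_CGN_{_COMP[up]}"
            for pos, name in plus.items():
                registers.setdefault((chrom, pos, "+"), name)
            for pos, name in minus.items():
                registers.setdefault((chrom, pos, "-"), name)

    names10 = (
        ["c_NCG_A", "c_NCG_C", "c_NCG_G", "c_NCG_T", "c_CGC", "c_GCG"]
        + ["c_CGN_A", "c_CGN_C", "c_CGN_G", "c_CGN_T"]
    )
    counts = {n: 0 for n in names10}
    for chrom, pos, strand, _motif in events:
        name = registers.get((chrom, pos, strand))
        if name is not None:
            counts[name] += 1
    total_ctx = sum(counts.values())
    for n in names10:
        feats[n] = counts[n] / total_ctx if total_ctx else 0.0
    ncg_sum = sum(counts[f"c_NCG_{b}"] for b in "ACGT")
    cgn_sum = sum(counts[f"c_CGN_{b}"] for b in "ACGT")
    if total_ctx:
        feats["c_CGC_over_NCG"] = counts["c_CGC"] / ncg_sum if ncg_sum else float(counts["c_CGC"])
        feats["c_CGN_over_CGC"] = cgn_sum / counts["c_CGC"] if counts["c_CGC"] else float(cgn_sum)
    else:
        feats["c_CGC_over_NCG"] = 0.0
        feats["c_CGN_over_CGC"] = 0.0
    return feats
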