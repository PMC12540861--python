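"""Naive quadratic reference implementation of the UMI consensus pipeline.

Deliberately brute-force and independent of the package internals: plain
Python string handling, all-pairs UMI comparisons, Counter-based consensus.
Used as the oracle that the production pipeline must match exactly.
"""

from collections import Counter


def parse_fastq(path):
    seqs = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for i in range(0, len(lines), 4):
        seqs.append(lines[i + 1])
    return seqs


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def naive_demux(seqs, umi_length, anchor, prefix_map, prefix_length):
    header = umi_length + len(anchor)
    assigned = []
    n_discard = 0
    for seq in seqs:
        if len(seq) < header + prefix_length:
            n_discard += 1
            continue
        if hamming(seq[umi_length:header], anchor) > 1:
            n_discard += 1
            continue
        payload = seq[header:]
        prefix = payload[:prefix_length]
        hits = [t for p, t in prefix_map.items() if hamming(prefix, p) <= 1]
        if len(hits) != 1:
            n_discard += 1
            continue
        assigned.append((hits[0], seq[:umi_length], payload))
    return assigned, n_discard


def naive_cluster(assigned, merge_ratio=0.1):
    """All-pairs directional merge; same declared rule, brute force."""
    by_target = {}
    for target, umi, payload in assigned:
        by_target.setdefault(target, {}).setdefault(umi, []).append(payload)
    families = {}
    for target in sorted(by_target):
        groups = by_target[target]
        original = {u: len(m) for u, m in groups.items()}
        order = sorted(groups, key=lambda u: (-original[u], u))
        kept = {}
        for umi in order:
            candidates = []
            for other in kept:
                if hamming(umi, other) <= 1 and original[umi] / original[other] <= merge_ratio:
                    candidates.append(other)
            if candidates:
                parent = sorted(candidates, key=lambda u: (-original[u], u))[0]
                kept[parent].extend(groups[umi])
            else:
                kept[umi] = list(groups[umi])
        for umi, members in kept.items():
            families[(target, umi)] = members
    return families


def naive_consensus(members, min_family_size=3, majority=0.75):
    length_counts = Counter(len(m) for m in members)
    top = max(length_counts.values())
    modal = min(l for l, c in length_counts.items() if c == top)
    kept = [m for m in members if len(m) == modal]
    if len(kept) < min_family_size:
        return None
    out = []
    for i in range(modal):
        counts = Counter(m[i] for m in kept if m[i] in "ACGT")
        if not counts:
            out.append("N")
            continue
        best = max(counts.values())
        winners = [b for b, c in counts.items() if c == best]
        if len(winners) > 1 or best < majority * len(kept):
            out.append("N")
        else:
            out.append(winners[0])
    return "".join(out)


def naive_counts(families, offsets, alleles, min_family_size=3, majority=0.75):
    counts = {t: [0, 0, 0] for t in offsets}  # total, mutant, other
    for (target, _umi), members in families.items():
        cons = naive_consensus(members, min_family_size, majority)
        if cons is None:
            continue
        base = cons[offsets[target]]
        if base == "N":
            continue
        ref, alt = alleles[target]
        counts[target][0] += 1
        if base == alt:
            counts[target][1] += 1
        elif base != ref:
            counts[target][2] += 1
    return {t: tuple(v) for t, v in counts.items()}


def naive_pipeline(fastq_path, panel, assay_sequences, umi_length, anchor,
                   prefix_length=16, min_family_size=3, majority=0.75,
                   merge_ratio=0.1):
    seqs = parse_fastq(fastq_path)
    prefix_map = {s[:prefix_length]: t for t, s in assay_sequences.items()}
    assigned, _ = naive_demux(seqs, umi_length, anchor, prefix_map, prefix_length)
    families = naive_cluster(assigned, merge_ratio=merge_ratio)
    offsets = {t.snv_id: panel.amplicon_offset(t.snv_id) for t in panel.targets}
    alleles = {t.snv_id: (t.ref, t.alt) for t in panel.targets}
    return naive_counts(families, offsets, alleles, min_family_size, majority)
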