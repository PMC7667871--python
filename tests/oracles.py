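"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's index/seed-and-extend machinery:
plain string scanning and per-offset comparisons only.
"""

from __future__ import annotations

from itertools import groupby

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def brute_force_map(genome: dict[str, str], seq: str, max_mismatches: int = 2):
    """Best ungapped location by scanning every offset of every strand.

    Returns ("unmapped", None), ("ambiguous", None) or
    ("unique", (replicon, start, strand, n_mismatches)).
    """
    best = None
    hits = []
    for strand in ("+", "-"):
        query = seq if strand == "+" else rc(seq)
        for replicon, template in genome.items():
            for start in range(len(template) - len(query) + 1):
                nmm = sum(
                    1 for a, b in zip(query, template[start : start + len(query)]) if a != b
                )
                if nmm <= max_mismatches:
                    hits.append((nmm, replicon, start, strand))
    if not hits:
        return "unmapped", None
    best = min(h[0] for h in hits)
    best_hits = [h for h in hits if h[0] == best]
    if len(best_hits) > 1:
        return "ambiguous", None
    nmm, replicon, start, strand = best_hits[0]
    return "unique", (replicon, start, strand, nmm)


def find_all(template: str, pattern: str) -> list[int]:
    out = []
    i = template.find(pattern)
    while i >= 0:
        out.append(i)
        i = template.find(pattern, i + 1)
    return out


def canonical(seq: str, cs: int, ce: int) -> tuple[int, int]:
    while cs > 0 and seq[cs - 1] == seq[ce - 1]:
        cs -= 1
        ce -= 1
    return cs, ce


def brute_force_junction(
    genome: dict[str, str],
    read: str,
    min_primary: int = 20,
    min_seed: int = 12,
    max_span: int = 4000,
):
    """Enumerative reimplementation of the two-pass junction contract.

    Mimics the published rules — longest primary fragment, anchored
    secondary fragment of >= min_seed nt with the single-positional and
    span requirements, permuted order — by scanning every split position
    with ``str.find``.  Returns a canonical (replicon, strand, cs, ce)
    tuple or None.
    """
    # pass 1: longest exact fragment anywhere, either strand
    best = None  # (-len, replicon, sstart, strand, qstart, qend)
    for strand in ("+", "-"):
        query = read if strand == "+" else rc(read)
        for replicon, template in genome.items():
            for qs in range(len(query)):
                for qe in range(len(query), qs + min_primary - 1, -1):
                    frag = query[qs:qe]
                    positions = find_all(template, frag)
                    if not positions:
                        continue
                    for sstart in positions:
                        # maximal only: not extendable on either side
                        if qs > 0 and sstart > 0 and query[qs - 1] == template[sstart - 1]:
                            continue
                        send = sstart + len(frag)
                        if (
                            qe < len(query)
                            and send < len(template)
                            and query[qe] == template[send]
                        ):
                            continue
                        cand = (-len(frag), replicon, sstart, strand, qs, qe)
                        if best is None or cand < best:
                            best = cand
                    break  # longer frag at this qs not possible
    if best is None:
        return None
    _, replicon, sstart, strand, qs, qe = best
    template = genome[replicon]
    query = read if strand == "+" else rc(read)
    send = sstart + (qe - qs)
    results = []
    # unaligned 3' flank: secondary anchored at the flank start
    flank = query[qe:]
    if len(flank) >= min_seed:
        seeds = find_all(template, flank[:min_seed])
        if len(seeds) == 1:
            pos = seeds[0]
            length = min_seed
            while (
                length < len(flank)
                and pos + length < len(template)
                and flank[length] == template[pos + length]
            ):
                length += 1
            s2, e2 = pos, pos + length
            dist = max(0, s2 - send) if s2 >= send else max(0, sstart - e2)
            if dist <= max_span and sstart > s2 and send - s2 <= max_span and s2 < send:
                results.append(canonical(template, s2, send))
    # unaligned 5' flank: secondary anchored at the flank end
    flank = query[:qs]
    if len(flank) >= min_seed:
        seeds = find_all(template, flank[-min_seed:])
        if len(seeds) == 1:
            pos = seeds[0]
            length = min_seed
            while (
                length < len(flank)
                and pos - (length - min_seed) > 0
                and flank[-(length + 1)] == template[pos - (length - min_seed) - 1]
            ):
                length += 1
            e2 = pos + min_seed
            s2 = e2 - length
            dist = max(0, sstart - e2) if e2 <= sstart else max(0, s2 - send)
            if dist <= max_span and s2 > sstart and e2 - sstart <= max_span and sstart < e2:
                results.append(canonical(template, sstart, e2))
    if not results:
        return None
    if len(set(results)) > 1:
        return None
    cs, ce = results[0]
    return (replicon, strand, cs, ce)


def longest_base_run(seq: str, base: str = "A") -> int:
    return max((len(list(g)) for b, g in groupby(seq) if b == base), default=0)
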