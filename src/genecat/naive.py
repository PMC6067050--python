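"""Naive reference implementations used as independent oracles.

Everything here is written with explicit loops over plain Python data,
deliberately sharing no code with the production modules, so that
equivalence tests between the two are meaningful.  The fixture generator
uses these to compute ground truth; the test suite uses them to check the
production implementations on randomized inputs.

Inputs are raw tuples/dicts, not the production dataclasses.
"""

from __future__ import annotations

from fractions import Fraction

RANKS = ("superkingdom", "phylum", "class", "order", "family",
         "genus", "species")

IDENTITY_FLOORS = (40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 95.0)


def gene_vote(hits, floors=IDENTITY_FLOORS):
    """Brute-force per-rank weighted majority for one gene.

    ``hits`` is a list of ``(pct_identity, align_len, query_len, lineage)``
    where ``lineage`` is a tuple of taxon keys from superkingdom down (any
    hashable key; length 0-7).  Returns ``(assigned_lineage, total_weight,
    support_per_depth)`` with the assigned lineage as a tuple of taxon keys.
    """
    weights = []
    for ident, alen, qlen, lineage in hits:
        frac = alen / qlen
        if frac > 1.0:
            frac = 1.0
        weights.append((frac * ident / 100.0, ident, lineage))
    total = 0.0
    for w, _i, _l in weights:
        total += w
    assigned = []
    support = []
    if total <= 0.0:
        return tuple(), total, []
    for depth in range(7):
        tally = {}
        for w, ident, lineage in weights:
            if len(lineage) <= depth:
                continue
            if ident < floors[depth]:
                continue
            taxon = lineage[depth]
            tally[taxon] = tally.get(taxon, 0.0) + w
        winner = None
        winner_w = -1.0
        for taxon in tally:
            if tally[taxon] > winner_w or (
                tally[taxon] == winner_w and str(taxon) > str(winner)
            ):
                winner = taxon
                winner_w = tally[taxon]
        if winner is None or not winner_w > 0.5 * total:
            break
        assigned.append(winner)
        support.append(winner_w / total)
    return tuple(assigned), total, support


def contig_vote(gene_results):
    """Brute-force contig consensus over gene vote results.

    ``gene_results`` is a list of ``(lineage_tuple, total_weight)`` per
    gene.  Unassigned genes (empty lineage) are ignored.  Returns
    ``(lineage_tuple, support_fraction)``.
    """
    voters = [(lin, w) for lin, w in gene_results if len(lin) > 0]
    denom = 0.0
    for _lin, w in voters:
        denom += w
    if not voters or denom <= 0.0:
        return tuple(), 0.0
    assigned = []
    support = 0.0
    for depth in range(7):
        tally = {}
        for lin, w in voters:
            if len(lin) <= depth:
                continue
            tally[lin[depth]] = tally.get(lin[depth], 0.0) + w
        if not tally:
            break
        winner = None
        winner_w = -1.0
        unique = True
        for taxon in sorted(tally, key=str):
            if tally[taxon] > winner_w:
                winner = taxon
                winner_w = tally[taxon]
                unique = True
            elif tally[taxon] == winner_w:
                unique = False
        if winner is None or winner_w < 0.5 * denom or not unique:
            break
        assigned.append(winner)
        support = winner_w / denom
    return tuple(assigned), support


def ec_majority(member_ec_sets, strict=True):
    """Brute-force strict-majority EC assignment for one group.

    ``member_ec_sets`` is a list of EC sets, one per member protein
    (possibly empty).  Members with no EC do not vote.
    """
    voters = [s for s in member_ec_sets if s]
    if not voters:
        return set()
    result = set()
    all_ecs = set()
    for s in voters:
        all_ecs |= s
    for ec in all_ecs:
        n = 0
        for s in voters:
            if ec in s:
                n += 1
        if strict:
            if 2 * n > len(voters):
                result.add(ec)
        else:
            if 2 * n >= len(voters):
                result.add(ec)
    return result


def dbcan_keep(hmm_from, hmm_to, model_len, ali_from, ali_to, ievalue,
               strict=False):
    """Brute-force application of the dbCAN domain rules."""
    coverage = (hmm_to - hmm_from + 1) / model_len
    ali_len = ali_to - ali_from + 1
    if not coverage > 0.3:
        return False
    if ali_len > 80:
        if not ievalue < 1e-5:
            return False
    else:
        if not ievalue < 1e-3:
            return False
    if strict:
        if not (ievalue < 1e-18 and coverage > 0.35):
            return False
    return True


def tpm_exact(counts, gene_lengths, read_length):
    """Exact-arithmetic TPM for one sample.

    ``counts``: dict gene -> integer count; ``gene_lengths``: dict gene ->
    nucleotide length; ``read_length``: mean read length (int, float or
    Fraction).  Returns dict gene -> Fraction.
    """
    rl = Fraction(str(read_length)) if not isinstance(
        read_length, Fraction) else read_length
    t = Fraction(0)
    for g in counts:
        t += Fraction(counts[g]) * rl / Fraction(gene_lengths[g])
    out = {}
    for g in counts:
        if t == 0:
            out[g] = Fraction(0)
        else:
            out[g] = (
                Fraction(counts[g]) * rl * Fraction(10**6)
                / (Fraction(gene_lengths[g]) * t)
            )
    return out


def top_score_keep(rows, max_evalue=1e-4):
    """Brute-force best-hit-per-gene selection.

    ``rows``: list of ``(gene, model, full_evalue, full_score)``.  Returns
    dict gene -> model.
    """
    out = {}
    for gene in {r[0] for r in rows}:
        candidates = [
            r for r in rows if r[0] == gene and r[2] <= max_evalue
        ]
        if not candidates:
            continue
        best_score = max(r[3] for r in candidates)
        best_models = sorted(
            r[1] for r in candidates if r[3] == best_score
        )
        out[gene] = best_models[0]
    return out
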