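"""Independent brute-force reference implementations used only by tests.

These deliberately use literal per-position loops and explicit lineage lists
so they share no code path with the package implementations they check.
"""

from __future__ import annotations


def brute_pass1(records, length):
    """Literal per-position pass-one: dict taxid -> per-position best s."""
    top = {}
    for r in records:
        s = r.bits / (r.q_end - r.q_start + 1)
        arr = top.setdefault(r.subject_taxid, [0.0] * length)
        for p in range(r.q_start - 1, r.q_end):
            if s > arr[p]:
                arr[p] = s
    global_top = [0.0] * length
    for arr in top.values():
        for p in range(length):
            if arr[p] > global_top[p]:
                global_top[p] = arr[p]
    scores = {t: sum(arr) for t, arr in top.items()}
    return top, global_top, scores


def brute_pass2(records, global_top, nt_exp, aa_exp):
    """Literal per-position pass-two volume accumulation."""
    volume = {}
    for r in records:
        s = r.bits / (r.q_end - r.q_start + 1)
        exp = nt_exp if r.kind == "nt" else aa_exp
        contrib = 0.0
        for p in range(r.q_start - 1, r.q_end):
            rel = min(s / global_top[p], 1.0)
            contrib += s * rel**exp
        volume[r.subject_taxid] = volume.get(r.subject_taxid, 0.0) + contrib
    return volume


def brute_lineage(parents, taxid):
    path = [taxid]
    while parents[path[-1]] != path[-1]:
        path.append(parents[path[-1]])
    return list(reversed(path))


def brute_lca(parents, a, b):
    """LCA by explicit lineage-list intersection."""
    la = brute_lineage(parents, a)
    lb = set(brute_lineage(parents, b))
    deepest = la[0]
    for x in la:
        if x in lb:
            deepest = x
    return deepest
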