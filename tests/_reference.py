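"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's graph machinery (networkx) and its
cached reachability: reachability is recomputed by explicit depth-first
enumeration over the raw edge map, and the selection rules are re-derived
from scratch, so agreement with the package oracle is a genuine
dual-route check.
"""

from __future__ import annotations


def _edge_map(model) -> dict[str, set[str]]:
    return {src: {d for d, _ in succs} for src, succs in model.edges.items()}


def _reachable_strict(edges, src, dst):
    # dst reachable from src through at least one edge
    if src == dst:
        return False
    stack, seen = list(edges.get(src, ())), set()
    while stack:
        node = stack.pop()
        if node == dst:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(edges.get(node, ()))
    return False


def brute_force_code(cert, model, apply_reject: bool = True):
    """Re-derivation of the rule pipeline with hand-rolled primitives.

    Returns (ucd_or_None, rejected_flag).
    """
    edges = _edge_map(model)
    positions = [
        (li, ci, code)
        for li, line in enumerate(cert.part1)
        for ci, code in enumerate(line)
    ]
    assert positions, "empty Part I"

    # general principle: single condition on the lowest used line that can
    # give rise to every condition above it
    selected = None
    lowest = cert.part1[-1]
    if len(lowest) == 1:
        c = lowest[0]
        above = [code for li, _, code in positions if li < len(cert.part1) - 1]
        if all(_reachable_strict(edges, c, a) for a in above):
            selected = c

    if selected is None:
        # fallback: origin of the first-mentioned causal sequence
        current_pos = positions[0]
        used = {current_pos[:2]}
        while True:
            best = None
            for li, ci, code in positions:
                if (li, ci) in used:
                    continue
                if current_pos[2] in edges.get(code, set()):
                    if best is None or (li, -ci) > (best[0], -best[1]):
                        best = (li, ci, code)
            if best is None:
                break
            current_pos = best
            used.add(best[:2])
        selected = current_pos[2]

    part1_codes = {code for _, _, code in positions}
    part2_codes = {c for line in cert.part2 for c in line}
    for trigger, pattern, ucd in model.promotion_pairs:
        if trigger in part2_codes and pattern in part1_codes:
            selected = ucd
            break

    if cert.demographics.age_bin == 0:
        selected = model.neonatal_map.get(selected, selected)

    threshold, remap = model.rule_change
    if cert.year >= threshold:
        selected = remap.get(selected, selected)

    if apply_reject:
        origins = {
            c for c in part1_codes
            if not any(c in edges.get(d, set()) for d in part1_codes if d != c)
        }
        if len(origins) > model.params.reject_max_origins:
            return None, True
    return selected, False
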