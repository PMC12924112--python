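"""Independent brute-force oracles, deliberately written without reusing the
package's own filtering/LCA/trimming code paths."""

from benthos16s.io_model import RANKS, FilterConfig, Lineage


def brute_force_lca(lineages):
    """Deepest rank depth at which every lineage agrees, scanned from deep
    to shallow over the whole hierarchy."""
    for depth in range(len(RANKS), 0, -1):
        prefixes = set()
        ok = True
        for lin in lineages:
            if lin.depth < depth:
                ok = False
                break
            prefixes.add(lin.names[:depth])
        if ok and len(prefixes) == 1:
            return Lineage(next(iter(prefixes)))
    return Lineage(())


def brute_force_assign(hits, config: FilterConfig):
    """Apply the documented filtering rules step by step, returning the final
    trimmed lineage (or empty)."""
    usable = [h for h in hits if h.lineage is not None]
    if config.low_score_rule == "or":
        kept = [
            h
            for h in usable
            if not (h.bitscore < config.bitscore_min)
            and not (h.alignment_length < config.alen_min)
        ]
    else:
        kept = [
            h
            for h in usable
            if not (
                h.bitscore < config.bitscore_min
                and h.alignment_length < config.alen_min
            )
        ]
    if not kept:
        return Lineage(())
    best = max(h.bitscore for h in kept)
    kept = [h for h in kept if h.bitscore >= (1 - config.margin_fraction) * best]
    lca = brute_force_lca([h.lineage for h in kept])
    identity = max(h.pct_identity for h in kept)
    # deepest permitted rank by scanning the ladder from species upward
    ladder = ["species", "genus", "family", "order", "class", "phylum"]
    permitted = 1 if config.retain_domain else 0
    for rank in ladder:
        if identity > config.identity_cutoffs[rank]:
            permitted = RANKS.index(rank) + 1
            break
    return Lineage(lca.names[:permitted])
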