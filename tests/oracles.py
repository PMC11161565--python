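"""Independent brute-force oracles used by unit and acceptance tests.

Pure-Python nested loops over AlleleCall views — deliberately disjoint from
the vectorized implementation paths they validate.
"""

from collections import Counter


def brute_catalog(table, pops, ancestors, strict=False):
    """taxon -> set of (site_id, allele) by exhaustive enumeration."""
    observed = {}
    for taxon in ancestors:
        seen = set()
        for ind in pops.members(taxon):
            for site in table.sites:
                call = table.call(ind, site.site_id)
                if not call.missing:
                    for a in call.alleles:
                        seen.add((site.site_id, a))
        observed[taxon] = seen
    typed_sites = None
    if strict:
        typed_sites = set()
        for site in table.sites:
            if all(
                any(not table.call(i, site.site_id).missing for i in pops.members(t))
                for t in ancestors
            ):
                typed_sites.add(site.site_id)
    out = {}
    for taxon in ancestors:
        others = set()
        for o in ancestors:
            if o != taxon:
                others |= observed[o]
        priv = observed[taxon] - others
        if strict:
            priv = {(s, a) for s, a in priv if s in typed_sites}
        out[taxon] = priv
    return out


def brute_trace(table, catalog_entries, targets):
    """(raw counts, n_variant_sites) by exhaustive enumeration."""
    raw = {}
    n_sites = {}
    for ind in targets:
        n = 0
        for site in table.sites:
            if not table.call(ind, site.site_id).missing:
                n += 1
        n_sites[ind] = n
        for taxon, pairs in catalog_entries.items():
            c = 0
            for site_id, allele in pairs:
                call = table.call(ind, site_id)
                if not call.missing and allele in call.alleles:
                    c += 1
            raw[(ind, taxon)] = c
    return raw, n_sites


def brute_attribute_extinct(table, pops, proxy_pop, extant):
    proxy_seen = set()
    for ind in pops.members(proxy_pop):
        for site in table.sites:
            call = table.call(ind, site.site_id)
            if not call.missing:
                proxy_seen |= {(site.site_id, a) for a in call.alleles}
    extant_seen = set()
    for taxon in extant:
        for ind in pops.members(taxon):
            for site in table.sites:
                call = table.call(ind, site.site_id)
                if not call.missing:
                    extant_seen |= {(site.site_id, a) for a in call.alleles}
    return proxy_seen - extant_seen


def brute_nearest_vertex_km(haversine, lat, lon, borderline):
    return min(haversine(lat, lon, blat, blon) for blat, blon in borderline)
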