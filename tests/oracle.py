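"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately coded from first principles (plain loops,
no numpy percentile, no reuse of the package's aggregation paths) so that
the main code can be checked against a second, independent route.
"""

from __future__ import annotations


def ref_domain_score(definition, domain_id, answers, floor=0.5):
    """Reference (raw, normalized) for one domain; (None, None) if missing.

    Recomputes every rule directly from the domain's declared fields.
    """
    dom = next(d for d in definition.domains if d.domain_id == domain_id)
    rule = dom.scoring_rule or definition.scoring_rule
    higher_better = (
        dom.higher_is_better
        if dom.higher_is_better is not None
        else definition.higher_is_better
    )
    got = [(it, answers.get(it.item_id)) for it in dom.items]
    present = [(it, v) for it, v in got if v is not None]

    if rule == "grade-rescale":
        raw = None
        resolved = True
        for it in sorted(dom.items, key=lambda i: -(i.grade or 0)):
            v = answers.get(it.item_id)
            if v is None:
                resolved = False
                break
            if v == max(c.code for c in it.levels):
                raw = float(it.grade)
                break
        else:
            raw = 0.0
        if not resolved and raw is None:
            raw = None
    elif rule == "passthrough-0-100":
        raw = float(present[0][1]) if present else None
    else:
        if len(present) == 0 or len(present) / len(dom.items) < floor:
            raw = None
        else:
            total = 0.0
            for _, v in present:
                total += v
            mean = total / len(present)
            raw = mean if rule == "mean-rescale" else mean * len(dom.items)

    if raw is None:
        return None, None
    span = dom.raw_max - dom.raw_min
    if higher_better:
        norm = 100.0 * (raw - dom.raw_min) / span
    else:
        norm = 100.0 * (dom.raw_max - raw) / span
    return raw, min(100.0, max(0.0, norm))


def ref_area_aggregate(mapping, scores):
    """Flat re-aggregation: area -> (mean, min) over non-missing members.

    ``scores`` maps (instrument_id, domain_id) to a normalized value or None.
    """
    out = {}
    for area in mapping.areas:
        vals = [scores[k] for k in area.members if scores[k] is not None]
        if vals:
            total = 0.0
            for v in vals:
                total += v
            lo = vals[0]
            for v in vals[1:]:
                if v < lo:
                    lo = v
            out[area.area_id] = (total / len(vals), lo)
        else:
            out[area.area_id] = (None, None)
    return out


def ref_percentile(values, p):
    """Type-7 percentile (linear interpolation between closest ranks)."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * p
    lo = int(h)
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def ref_sort_rows(rows):
    """Comparison-sort oracle for the extent/frequency table ordering."""
    import functools

    def cmp(a, b):
        am = a.median if a.median is not None else float("inf")
        bm = b.median if b.median is not None else float("inf")
        if am != bm:
            return -1 if am < bm else 1
        af = a.frequency if a.frequency is not None else -1.0
        bf = b.frequency if b.frequency is not None else -1.0
        if af != bf:
            return -1 if af > bf else 1
        return -1 if a.domain_id < b.domain_id else (1 if a.domain_id > b.domain_id else 0)

    return sorted(rows, key=functools.cmp_to_key(cmp))
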