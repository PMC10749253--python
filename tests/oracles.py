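"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (flood fill / explicit set algebra /
hand tallies) and shares no code with the package paths it checks.
"""

import numpy as np


def flood_fill_components(mask):
    """Count maximal 4-connected foreground regions by stack-based flood fill."""
    mask = np.asarray(mask).astype(bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    n = 0
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            n += 1
            stack = [(sy, sx)]
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                            and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
    return n


def aji_by_set_algebra(pred_map, gt_map):
    """Aggregated Jaccard index via explicit pixel-set operations.

    Ground-truth objects are processed in ascending label order; each is
    matched to the unused intersecting prediction of highest IoU (ties to
    the lower prediction label); unmatched prediction areas join the union.
    """
    pred_map = np.asarray(pred_map)
    gt_map = np.asarray(gt_map)
    pred_sets = {
        int(j): set(map(tuple, np.argwhere(pred_map == j)))
        for j in np.unique(pred_map) if j > 0
    }
    gt_sets = {
        int(g): set(map(tuple, np.argwhere(gt_map == g)))
        for g in np.unique(gt_map) if g > 0
    }
    used = set()
    inter_sum = union_sum = 0
    for g in sorted(gt_sets):
        best_iou, best_j = 0.0, None
        for j in sorted(pred_sets):
            if j in used:
                continue
            inter = len(gt_sets[g] & pred_sets[j])
            if inter == 0:
                continue
            iou = inter / len(gt_sets[g] | pred_sets[j])
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j is None:
            union_sum += len(gt_sets[g])
        else:
            used.add(best_j)
            inter_sum += len(gt_sets[g] & pred_sets[best_j])
            union_sum += len(gt_sets[g] | pred_sets[best_j])
    for j, pixels in pred_sets.items():
        if j not in used:
            union_sum += len(pixels)
    if union_sum == 0:
        return 1.0
    return inter_sum / union_sum


def hand_logrank(t1, e1, t2, e2):
    """Two-group log-rank chi-square by explicit observed-minus-expected tally."""
    times = np.concatenate([t1, t2]).astype(float)
    events = np.concatenate([e1, e2]).astype(int)
    grp = np.concatenate([np.zeros(len(t1), int), np.ones(len(t2), int)])
    obs = exp = var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (grp == 0)).sum()
        obs += d1
        exp += n1 * d / n
        if n > 1:
            var += n1 * (n - n1) * d * (n - d) / (n**2 * (n - 1))
    return (obs - exp) ** 2 / var


def pixelwise_cross_entropy(p, t):
    """Plain binary cross-entropy by an explicit per-pixel Python loop."""
    total = 0.0
    eps = 1e-7
    for pi, ti in zip(np.ravel(p), np.ravel(t)):
        pi = min(max(pi, eps), 1 - eps)
        total += -(ti * np.log(pi) + (1 - ti) * np.log(1 - pi))
    return total / np.size(p)
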