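"""Independent brute-force oracles used to validate the vectorized code.

Everything here is written as plain nested loops over voxels and supervoxels,
deliberately sharing no code with the package implementation.
"""

import numpy as np


def brute_force_assign(intensity, mask, spatial_centres, colour_centres,
                       spacing, compactness, windowed=False):
    """Nearest-centre labels over all (voxel, centre) pairs under D_w.

    With ``windowed=True`` only centres whose 2*spacing cube contains the
    voxel are candidates (voxels with no candidate fall back to the global
    minimum).  Ties go to the lower centre index (first strict minimum).
    """

    def dw_of(x, y, z, k):
        ds2 = sum((p - c) ** 2 for p, c in zip((x, y, z), spatial_centres[k]))
        dc2 = sum(
            (intensity[x, y, z, c] - colour_centres[k][c]) ** 2 for c in range(3)
        )
        return np.sqrt(dc2 / compactness**2 + ds2 / spacing**2)

    def in_window(x, y, z, k):
        c = np.round(spatial_centres[k]).astype(int)
        return all(abs(p - ci) <= spacing for p, ci in zip((x, y, z), c))

    labels = np.full(mask.shape, -1, dtype=int)
    for x in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            for z in range(mask.shape[2]):
                if not mask[x, y, z]:
                    continue
                candidates = [
                    k for k in range(len(spatial_centres))
                    if not windowed or in_window(x, y, z, k)
                ] or list(range(len(spatial_centres)))
                best, best_k = np.inf, -1
                for k in candidates:
                    dw = dw_of(x, y, z, k)
                    if dw < best:
                        best, best_k = dw, k
                labels[x, y, z] = best_k
    return labels


def brute_force_expanse_mean_of_sds(labels, volumes, n_labels):
    """Two-pass per-supervoxel population sd, averaged over supervoxels."""
    out = []
    for vol in volumes:
        sds = []
        for j in range(n_labels):
            vals = [
                float(vol.data[x, y, z])
                for x in range(labels.shape[0])
                for y in range(labels.shape[1])
                for z in range(labels.shape[2])
                if labels[x, y, z] == j
            ]
            mean = sum(vals) / len(vals)
            var = sum((v - mean) ** 2 for v in vals) / len(vals)
            sds.append(np.sqrt(var))
        out.append(sum(sds) / n_labels)
    return np.array(out)


def brute_force_supervoxel_means(labels, volume, n_labels):
    means = []
    for j in range(n_labels):
        vals = [
            float(volume.data[x, y, z])
            for x in range(labels.shape[0])
            for y in range(labels.shape[1])
            for z in range(labels.shape[2])
            if labels[x, y, z] == j
        ]
        means.append(sum(vals) / len(vals))
    return np.array(means)


def brute_force_similarity(labels, volumes, expanse_values, n_labels):
    """Per-voxel evaluation: S2 = 1 iff |I - supervoxel mean| < E for ALL tissues."""
    means = [brute_force_supervoxel_means(labels, v, n_labels) for v in volumes]
    s2 = np.zeros(labels.shape, dtype=np.uint8)
    for x in range(labels.shape[0]):
        for y in range(labels.shape[1]):
            for z in range(labels.shape[2]):
                j = labels[x, y, z]
                if j < 0:
                    continue
                ok = True
                for c, vol in enumerate(volumes):
                    dt = abs(float(vol.data[x, y, z]) - means[c][j])
                    if not (dt < expanse_values[c]):
                        ok = False
                        break
                s2[x, y, z] = 1 if ok else 0
    return s2


def brute_force_histon(volume, s2, mask, levels=256):
    """Triple-loop histon and histogram."""
    histon = np.zeros(levels, dtype=np.int64)
    histogram = np.zeros(levels, dtype=np.int64)
    for x in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            for z in range(mask.shape[2]):
                if not mask[x, y, z]:
                    continue
                g = int(volume.data[x, y, z])
                histogram[g] += 1
                histon[g] += 1 + int(s2[x, y, z])
    return histon, histogram


def brute_force_classic_histon_2d(image, P, Q, expanse, levels=256):
    """Hand-loop classic histon for a 2D single-channel image."""
    M, N = image.shape
    histon = np.zeros(levels, dtype=np.int64)
    histogram = np.zeros(levels, dtype=np.int64)
    for x in range(M):
        for y in range(N):
            dt = 0.0
            for p in range(-(P // 2), P // 2 + 1):
                for q in range(-(Q // 2), Q // 2 + 1):
                    if p == 0 and q == 0:
                        continue
                    xx, yy = x + p, y + q
                    if 0 <= xx < M and 0 <= yy < N:
                        dt += (float(image[x, y]) - float(image[xx, yy])) ** 2
            s = 1 if dt < expanse else 0
            g = int(image[x, y])
            histogram[g] += 1
            histon[g] += 1 + s
    return histon, histogram
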