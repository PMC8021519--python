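"""Color normalization and stack-global rigid registration of serial sections.

Serial paraffin sections land on the slide with independent rigid offsets.
Registration here follows the sparse, stack-global recipe: extract the
deconvolved blue (CD34) channel, blur it with a sigma-6 Gaussian, detect
point features on the blurred channel, match each section against its k
nearest z-neighbours with robust (RANSAC) pair estimation, then jointly
refine all per-section rigid transforms by Huber-weighted Gauss–Newton with
the reference section pinned to the identity.  The established transforms
are finally applied to the non-blurred RGB sections.

Colors are first normalized to a single reference image by Reinhard's
statistics transfer in the decorrelated lαβ space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import ransac
from skimage.transform import EuclideanTransform, warp

from .phantom import SectionImage
from .stain import StainModel
from .unmixing import color_deconvolve

__all__ = [
    "StackAlignment",
    "lab_stats",
    "reinhard_normalize",
    "extract_registration_channel",
    "register_stack",
    "apply_alignment",
    "RegistrationError",
]


class RegistrationError(RuntimeError):
    pass


# Ruderman lαβ color space (log-LMS decorrelation), per Reinhard et al.
_RGB2LMS = np.array(
    [[0.3811, 0.5783, 0.0402], [0.1967, 0.7244, 0.0782], [0.0241, 0.1288, 0.8444]]
)
_LMS2LAB_A = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)])
_LMS2LAB_B = np.array([[1, 1, 1], [1, 1, -2], [1, -1, 0]])
_LMS2LAB = _LMS2LAB_A @ _LMS2LAB_B
_LAB2LMS = np.linalg.inv(_LMS2LAB)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LOG_EPS = 1.0  # guard for log10 of dark pixels, on the 0-255 scale


def _rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    lms = np.clip(rgb, 0, 255) @ _RGB2LMS.T
    return np.log10(lms + _LOG_EPS) @ _LMS2LAB.T


def _lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    lms = np.power(10.0, lab @ _LAB2LMS.T) - _LOG_EPS
    return lms @ _LMS2RGB.T


def lab_stats(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (mean, std) of an RGB image in lαβ space."""
    lab = _rgb_to_lab(np.asarray(image, dtype=float).reshape(-1, 3))
    return lab.mean(axis=0), lab.std(axis=0)


def reinhard_normalize(
    image: SectionImage | np.ndarray,
    reference_stats: tuple[np.ndarray, np.ndarray],
) -> SectionImage | np.ndarray:
    """Transfer lαβ channel statistics of a reference onto ``image``.

    Each lαβ channel is mapped ``(x - mu_img) * (sigma_ref / sigma_img) +
    mu_ref``; a channel with zero spread is set to the reference mean.  The
    result is converted back to RGB and clipped to [0, 255].
    """
    mu_ref, sd_ref = (np.asarray(a, dtype=float) for a in reference_stats)
    if not (np.all(np.isfinite(mu_ref)) and np.all(np.isfinite(sd_ref))):
        raise ValueError("reference stats must be finite")
    if np.any(sd_ref <= 0):
        raise ValueError("reference stds must be positive")
    pixels = image.pixels if isinstance(image, SectionImage) else image
    orig_dtype = pixels.dtype
    lab = _rgb_to_lab(np.asarray(pixels, dtype=float))
    mu = lab.reshape(-1, 3).mean(axis=0)
    sd = lab.reshape(-1, 3).std(axis=0)
    # a channel with (numerically) zero spread is set to the reference mean
    degenerate = sd <= 1e-9
    scale = np.where(degenerate, 0.0, sd_ref / np.where(degenerate, 1.0, sd))
    lab = (lab - mu) * scale + mu_ref
    rgb = np.clip(_lab_to_rgb(lab), 0.0, 255.0)
    if orig_dtype == np.uint8:
        rgb = np.rint(rgb).astype(np.uint8)
    if isinstance(image, SectionImage):
        import dataclasses

        return dataclasses.replace(image, pixels=rgb)
    return rgb


def extract_registration_channel(
    image: SectionImage | np.ndarray,
    stain_model: StainModel,
    sigma: float = 6.0,
) -> np.ndarray:
    """Deconvolved blue (CD34) density, Gaussian-blurred for registration."""
    pixels = image.pixels if isinstance(image, SectionImage) else image
    dens = color_deconvolve(np.asarray(pixels, dtype=float), stain_model)
    blue = dens[..., 1]
    if sigma > 0:
        blue = ndimage.gaussian_filter(blue, sigma)
    return blue


# ---------------------------------------------------------------------------
# feature detection and matching


def _detect_peaks(channel: np.ndarray, max_peaks: int, min_distance: int,
                  abs_threshold: float, min_roundness: float = 0.25
                  ) -> np.ndarray:
    """Well-localized blob centroids (x, y), subpixel refined.

    Peaks on elongated ridges (vessels running obliquely through the
    section) are poorly localized along the ridge and their apparent
    position drifts quickly from section to section; they are rejected by a
    cornerness criterion — the ratio of the Hessian eigenvalues at the peak
    must exceed ``min_roundness``, i.e. only blob-like maxima survive.
    """
    coords = peak_local_max(
        channel,
        min_distance=min_distance,
        threshold_abs=abs_threshold,
        num_peaks=max_peaks,
        exclude_border=min_distance + 1,
    )
    pts = []
    for r, c in coords:
        # Hessian from central differences at the blurred peak
        hrr = channel[r - 1, c] - 2 * channel[r, c] + channel[r + 1, c]
        hcc = channel[r, c - 1] - 2 * channel[r, c] + channel[r, c + 1]
        hrc = 0.25 * (channel[r + 1, c + 1] - channel[r + 1, c - 1]
                      - channel[r - 1, c + 1] + channel[r - 1, c - 1])
        tr = hrr + hcc
        det = hrr * hcc - hrc * hrc
        disc = max(tr * tr - 4 * det, 0.0)
        l1 = 0.5 * (tr - np.sqrt(disc))  # most negative (sharpest) curvature
        l2 = 0.5 * (tr + np.sqrt(disc))
        if l1 >= 0 or l2 >= 0 or (l2 / l1) < min_roundness:
            continue  # ridge-like or saddle: drop
        # parabolic subpixel refinement on the 3x3 neighbourhood of the peak
        w = channel[r - 1:r + 2, c - 1:c + 2]
        denom_y = w[0, 1] - 2 * w[1, 1] + w[2, 1]
        denom_x = w[1, 0] - 2 * w[1, 1] + w[1, 2]
        dy = 0.5 * (w[0, 1] - w[2, 1]) / denom_y if denom_y < 0 else 0.0
        dx = 0.5 * (w[1, 0] - w[1, 2]) / denom_x if denom_x < 0 else 0.0
        pts.append((c + np.clip(dx, -0.5, 0.5), r + np.clip(dy, -0.5, 0.5)))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def _patch(channel: np.ndarray, x: float, y: float, half: int) -> np.ndarray | None:
    r, c = int(round(y)), int(round(x))
    if (r - half < 0 or c - half < 0 or r + half + 1 > channel.shape[0]
            or c + half + 1 > channel.shape[1]):
        return None
    p = channel[r - half:r + half + 1, c - half:c + half + 1].astype(float)
    p = p - p.mean()
    n = np.linalg.norm(p)
    return p / n if n > 0 else None


def _match_pair(
    chan_a: np.ndarray,
    pts_a: np.ndarray,
    chan_b: np.ndarray,
    pts_b: np.ndarray,
    search_radius: float,
    patch_half: int,
    ratio: float,
) -> tuple[np.ndarray, np.ndarray]:
    """NCC patch matching with a Lowe-style ratio test; returns point pairs."""
    if len(pts_a) == 0 or len(pts_b) == 0:
        return np.empty((0, 2)), np.empty((0, 2))
    src, dst = [], []
    patches_b = [_patch(chan_b, x, y, patch_half) for x, y in pts_b]
    for x, y in pts_a:
        pa = _patch(chan_a, x, y, patch_half)
        if pa is None:
            continue
        d = np.linalg.norm(pts_b - np.array([x, y]), axis=1)
        cand = np.where(d <= search_radius)[0]
        scores = []
        for j in cand:
            pb = patches_b[j]
            scores.append(-np.inf if pb is None else float(np.sum(pa * pb)))
        if not scores:
            continue
        order = np.argsort(scores)[::-1]
        best = cand[order[0]]
        if scores[order[0]] < 0.5:
            continue
        if len(order) > 1 and scores[order[1]] > ratio * scores[order[0]]:
            continue  # ambiguous match
        src.append((x, y))
        dst.append(tuple(pts_b[best]))
    return np.asarray(src).reshape(-1, 2), np.asarray(dst).reshape(-1, 2)


def _refine_offset(chan_a: np.ndarray, pa: np.ndarray, chan_b: np.ndarray,
                   pb: np.ndarray, half: int = 10, search: int = 3
                   ) -> np.ndarray | None:
    """Subpixel refinement of a match: local NCC search around ``pb``.

    Slides the patch at ``pa`` (section a) over integer offsets within
    ``±search`` of ``pb`` (section b) and interpolates the NCC maximum
    parabolically.  Returns the refined partner position in b, or None when
    either patch leaves the image.
    """
    ref = _patch(chan_a, pa[0], pa[1], half)
    if ref is None:
        return None
    rb, cb = int(round(pb[1])), int(round(pb[0]))
    lo_r, hi_r = rb - half - search, rb + half + search + 1
    lo_c, hi_c = cb - half - search, cb + half + search + 1
    if lo_r < 0 or lo_c < 0 or hi_r > chan_b.shape[0] or hi_c > chan_b.shape[1]:
        return None
    win = chan_b[lo_r:hi_r, lo_c:hi_c].astype(float)
    size = 2 * half + 1
    ncc = np.empty((2 * search + 1, 2 * search + 1))
    for dr in range(2 * search + 1):
        for dc in range(2 * search + 1):
            p = win[dr:dr + size, dc:dc + size]
            p = p - p.mean()
            nrm = np.linalg.norm(p)
            ncc[dr, dc] = float(np.sum(ref * p) / nrm) if nrm > 0 else -np.inf
    r0, c0 = np.unravel_index(np.argmax(ncc), ncc.shape)
    if not (0 < r0 < 2 * search and 0 < c0 < 2 * search):
        return None
    if ncc[r0, c0] >= 1.0 - 1e-9:
        # exact copy: the integer displacement is the answer; parabolic
        # interpolation would add a spurious sub-pixel offset
        return pa + np.array([cb + c0 - search - round(pa[0]),
                              rb + r0 - search - round(pa[1])], dtype=float)
    denom_r = ncc[r0 - 1, c0] - 2 * ncc[r0, c0] + ncc[r0 + 1, c0]
    denom_c = ncc[r0, c0 - 1] - 2 * ncc[r0, c0] + ncc[r0, c0 + 1]
    sub_r = 0.5 * (ncc[r0 - 1, c0] - ncc[r0 + 1, c0]) / denom_r if denom_r < 0 else 0.0
    sub_c = 0.5 * (ncc[r0, c0 - 1] - ncc[r0, c0 + 1]) / denom_c if denom_c < 0 else 0.0
    dr = r0 - search + np.clip(sub_r, -0.5, 0.5)
    dc = c0 - search + np.clip(sub_c, -0.5, 0.5)
    return np.array([cb + dc, rb + dr], dtype=float)


@dataclass
class StackAlignment:
    """Per-section planar rigid transforms into the common (reference) frame.

    ``transforms[k]`` maps pixel coordinates of section ``k`` into the frame
    of the reference section; the reference transform is the identity (gauge
    fixing).
    """

    thetas: np.ndarray  # radians, per section
    translations: np.ndarray  # (n, 2) px
    reference_index: int
    residual_stats: dict = field(default_factory=dict)

    def transform(self, k: int) -> EuclideanTransform:
        return EuclideanTransform(
            rotation=self.thetas[k], translation=self.translations[k]
        )

    def apply_points(self, k: int, pts: np.ndarray) -> np.ndarray:
        return self.transform(k)(pts)

    @property
    def n_sections(self) -> int:
        return len(self.thetas)


def _pair_ransac(src, dst, residual_threshold, rng):
    if len(src) < 3:
        return None
    try:
        model, inliers = ransac(
            (src, dst),
            EuclideanTransform,
            min_samples=2,
            residual_threshold=residual_threshold,
            max_trials=300,
            rng=rng,
        )
    except Exception:
        return None
    if model is None or inliers is None or inliers.sum() < 3:
        return None
    return src[inliers], dst[inliers]


def register_stack(
    channels: list[np.ndarray],
    reference_index: int | None = None,
    k_neighbors: int = 2,
    max_peaks: int = 250,
    min_distance: int = 4,
    abs_threshold: float = 0.02,
    search_radius: float = 28.0,
    patch_half: int = 10,
    ratio: float = 0.92,
    residual_threshold: float = 2.0,
    huber_delta: float = 1.5,
    min_matches: int = 4,
    gn_iterations: int = 30,
    rematch_neighbors: int = 6,
    seed: int = 0,
) -> StackAlignment:
    """Recover per-section rigid transforms from blurred blue channels.

    Features are blob centroids of the registration channel (subpixel
    refined); each section is matched to its ``k_neighbors`` nearest
    z-neighbours with an NCC ratio test and RANSAC pair filtering, and all
    transforms are then refined jointly by minimizing the Huber-weighted sum
    of squared reprojection residuals over the whole stack with the
    reference section fixed to the identity.
    """
    n = len(channels)
    if n < 2:
        raise RegistrationError("need at least two sections")
    if reference_index is None:
        reference_index = n // 2
    rng = np.random.default_rng(seed)

    pts = [
        _detect_peaks(np.asarray(c, dtype=float), max_peaks, min_distance, abs_threshold)
        for c in channels
    ]
    for i, p in enumerate(pts):
        if len(p) == 0:
            raise RegistrationError(f"no detectable features in section {i}")

    # pairwise matches (i < j), robustly filtered
    matches: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for i in range(n):
        for j in range(i + 1, min(i + k_neighbors + 1, n)):
            src, dst = _match_pair(
                channels[i], pts[i], channels[j], pts[j],
                search_radius * (j - i), patch_half, ratio,
            )
            got = _pair_ransac(src, dst, residual_threshold * (j - i), rng)
            if got is not None:
                matches[(i, j)] = got

    # solve in image-centered coordinates: rotation about the image center
    # decorrelates the angle from the translation in the normal equations
    h, w = channels[0].shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    pts = [p - center for p in pts]
    matches = {k: (s - center, d - center) for k, (s, d) in matches.items()}

    # every section must be matched to at least one neighbour
    linked = {reference_index}
    adjacency: dict[int, list[int]] = {i: [] for i in range(n)}
    for (i, j), (src, _dst) in matches.items():
        if len(src) >= min_matches:
            adjacency[i].append(j)
            adjacency[j].append(i)
    for i in range(n):
        if not adjacency[i]:
            raise RegistrationError(
                f"section {i} has fewer than {min_matches} matches to any "
                "neighbour; mark it lost or relax detection"
            )

    # initialize by chaining pairwise estimates outward from the reference
    thetas = np.zeros(n)
    trans = np.zeros((n, 2))
    visited = {reference_index}
    import heapq

    heap = [(0, reference_index)]
    pair_models: dict[tuple[int, int], EuclideanTransform] = {}
    for (i, j), (src, dst) in matches.items():
        m = EuclideanTransform.from_estimate(src, dst)
        if m:
            pair_models[(i, j)] = m
    while heap:
        _, i = heapq.heappop(heap)
        for j in adjacency[i]:
            if j in visited:
                continue
            key, forward = ((i, j), False) if (i, j) in pair_models else ((j, i), True)
            if key not in pair_models:
                continue
            m = pair_models[key]
            # model maps key[0] coords -> key[1] coords
            t_i = EuclideanTransform(rotation=thetas[i], translation=trans[i])
            rel = (m.inverse if not forward else m)
            # want T_j with T_j = T_i o (j -> i map)
            comp = rel + t_i  # applies rel first, then t_i
            thetas[j] = comp.rotation
            trans[j] = comp.translation
            visited.add(j)
            heapq.heappush(heap, (abs(j - reference_index), j))
    if len(visited) < n:
        missing = sorted(set(range(n)) - visited)
        raise RegistrationError(f"sections {missing} not connected to the reference")

    # joint Gauss-Newton refinement with Huber weights
    pair_list = [(i, j, src, dst) for (i, j), (src, dst) in matches.items()]
    thetas, trans = _solve_global(
        pair_list, n, reference_index, thetas, trans, huber_delta, gn_iterations
    )

    # transform-guided re-matching: with the stack roughly aligned, rebuild
    # the match set by mutual nearest neighbours in the common frame.  This
    # recovers matches the appearance stage missed (and with them, the
    # drift-cancelling symmetric feature pairs), then re-solves.
    # transform-guided re-matching: with the stack roughly aligned, rebuild
    # the match set by mutual nearest neighbours in the common frame and
    # re-localize partners by local NCC (peak centroids are noisy in a
    # crowded blurred field), then re-solve at shrinking gating radii.
    def _rematch(radius_of_dz, k_max, refine):
        pair_list = []
        for i in range(n):
            for j in range(i + 1, min(i + k_max + 1, n)):
                rad = radius_of_dz(j - i)
                Ti = EuclideanTransform(rotation=thetas[i], translation=trans[i])
                Tj = EuclideanTransform(rotation=thetas[j], translation=trans[j])
                ai, aj = Ti(pts[i]), Tj(pts[j])
                d = np.linalg.norm(ai[:, None, :] - aj[None, :, :], axis=2)
                nn_ij = np.argmin(d, axis=1)
                nn_ji = np.argmin(d, axis=0)
                sel = [
                    (a, b)
                    for a, b in enumerate(nn_ij)
                    if nn_ji[b] == a and d[a, b] <= rad
                ]
                if len(sel) < min_matches:
                    continue
                src_pts, dst_pts = [], []
                for a, b in sel:
                    dst = pts[j][b]
                    if refine and j - i <= 2:
                        q = _refine_offset(
                            channels[i], pts[i][a] + center,
                            channels[j], dst + center, half=patch_half,
                        )
                        if q is not None:
                            dst = q - center
                    src_pts.append(pts[i][a])
                    dst_pts.append(dst)
                pair_list.append((i, j, np.asarray(src_pts), np.asarray(dst_pts)))
        return pair_list

    for radius in (7.0, 4.0, 3.0):
        pair_list = _rematch(lambda dz, r=radius: r * dz, k_neighbors, True)
        thetas, trans = _solve_global(
            pair_list, n, reference_index, thetas, trans, huber_delta, gn_iterations
        )

    # final pass: tightly gated long-range pairs.  Vessels running nearly
    # along z persist over many sections with small symmetric drift; pairs
    # up to `rematch_neighbors` sections apart anchor the stack against the
    # rotation random walk that nearest-neighbour chains accumulate.
    # the gate stays generous (4 px + 1.5 px per section of z distance):
    # a hard tight gate would discard exactly the peripheral matches that
    # constrain rotation and freeze any residual twist in place
    pair_list = _rematch(lambda dz: 4.0 + 1.5 * dz, rematch_neighbors, True)
    thetas, trans = _solve_global(
        pair_list, n, reference_index, thetas, trans, min(huber_delta, 1.2),
        gn_iterations,
    )

    # residual statistics per pair
    stats = {}
    for (i, j, src, dst) in pair_list:
        Ti = EuclideanTransform(rotation=thetas[i], translation=trans[i])
        Tj = EuclideanTransform(rotation=thetas[j], translation=trans[j])
        res = Ti(src) - Tj(dst)
        stats[(i, j)] = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))

    # back to pixel coordinates: p' = R (p - c) + t + c
    trans_px = np.empty_like(trans)
    for i in range(n):
        c_, s_ = np.cos(thetas[i]), np.sin(thetas[i])
        R = np.array([[c_, -s_], [s_, c_]])
        trans_px[i] = trans[i] + center - R @ center
    return StackAlignment(
        thetas=thetas,
        translations=trans_px,
        reference_index=reference_index,
        residual_stats={"pair_rms_px": stats,
                        "mean_rms_px": float(np.mean(list(stats.values())))
                        if stats else np.nan},
    )


def _solve_global(pair_list, n, reference_index, thetas, trans, huber_delta,
                  gn_iterations):
    """Huber-weighted Gauss-Newton over all per-section rigid transforms."""
    thetas = thetas.copy()
    trans = trans.copy()
    param_index = {}
    k = 0
    for i in range(n):
        if i != reference_index:
            param_index[i] = k
            k += 1
    n_params = 3 * k

    for _ in range(gn_iterations):
        JTJ = np.zeros((n_params, n_params))
        JTr = np.zeros(n_params)
        for (i, j, src, dst) in pair_list:
            ci, si = np.cos(thetas[i]), np.sin(thetas[i])
            cj, sj = np.cos(thetas[j]), np.sin(thetas[j])
            pi = src @ np.array([[ci, si], [-si, ci]]) + trans[i]
            pj = dst @ np.array([[cj, sj], [-sj, cj]]) + trans[j]
            res = pi - pj
            rnorm = np.linalg.norm(res, axis=1)
            wgt = np.where(rnorm <= huber_delta, 1.0,
                           np.sqrt(huber_delta / np.maximum(rnorm, 1e-12)))

            def jac_block(idx, pts2, sign):
                c, s = np.cos(thetas[idx]), np.sin(thetas[idx])
                dx = pts2[:, 0] * -s - pts2[:, 1] * c
                dy = pts2[:, 0] * c - pts2[:, 1] * s
                J = np.zeros((len(pts2), 2, 3))
                J[:, 0, 0] = sign * dx
                J[:, 1, 0] = sign * dy
                J[:, 0, 1] = sign
                J[:, 1, 2] = sign
                return J

            blocks = []
            if i != reference_index:
                blocks.append((param_index[i], jac_block(i, src, +1.0)))
            if j != reference_index:
                blocks.append((param_index[j], jac_block(j, dst, -1.0)))
            for bi, (pi_idx, Ji) in enumerate(blocks):
                Jw = Ji * wgt[:, None, None]
                rw = res * wgt[:, None]
                sl_i = slice(3 * pi_idx, 3 * pi_idx + 3)
                JTr[sl_i] += np.einsum("nij,ni->j", Jw, rw)
                for pj_idx, Jj in blocks[bi:]:
                    Jjw = Jj * wgt[:, None, None]
                    block = np.einsum("nij,nik->jk", Jw, Jjw)
                    sl_j = slice(3 * pj_idx, 3 * pj_idx + 3)
                    JTJ[sl_i, sl_j] += block
                    if pj_idx != pi_idx:
                        JTJ[sl_j, sl_i] += block.T
        try:
            delta = np.linalg.solve(JTJ + 1e-9 * np.eye(n_params), -JTr)
        except np.linalg.LinAlgError:
            break
        for i, pi_idx in param_index.items():
            thetas[i] += delta[3 * pi_idx]
            trans[i] += delta[3 * pi_idx + 1:3 * pi_idx + 3]
        if np.max(np.abs(delta)) < 1e-8:
            break
    return thetas, trans


def apply_alignment(
    images: list[SectionImage],
    alignment: StackAlignment,
    crop_px: int | None = None,
) -> list[SectionImage]:
    """Resample RGB sections into the common frame; optional central crop.

    Bilinear resampling with white background fill, then a central crop to
    ``crop_px`` square (the acquisition selects a centered sub-window of the
    registered frame).
    """
    import dataclasses

    if alignment.n_sections != len(images):
        raise ValueError("alignment does not cover all sections")
    out = []
    for k, im in enumerate(images):
        T = alignment.transform(k)
        px = np.asarray(im.pixels, dtype=float)
        warped = warp(px, inverse_map=T.inverse, order=1, cval=255.0,
                      mode="constant", preserve_range=True)
        if crop_px is not None:
            h, w = warped.shape[:2]
            if crop_px > h or crop_px > w:
                raise ValueError("crop larger than image")
            r0 = (h - crop_px) // 2
            c0 = (w - crop_px) // 2
            warped = warped[r0:r0 + crop_px, c0:c0 + crop_px]
        if im.pixels.dtype == np.uint8:
            warped = np.rint(np.clip(warped, 0, 255)).astype(np.uint8)
        out.append(dataclasses.replace(im, pixels=warped))
    return out
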