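"""Local raster filters: region-masked circular median and tiled application.

The transmittance image is smoothed with a circular median filter before it
enters any histogram or inclination formula.  To keep HM/LM borders sharp,
the filter can be restricted so each pixel's footprint only sees pixels of
the same region label (background excluded entirely).  ``chunked_apply``
tiles any such local operator over a large image with overlapping halos,
reproducing the whole-image result exactly.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["disk_offsets", "masked_median_filter", "median_filter_disk", "chunked_apply"]


def disk_offsets(radius: int) -> np.ndarray:
    """(dy, dx) offsets of a discrete disk footprint (centre distance <= radius)."""
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= r**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def masked_median_filter(
    image: np.ndarray,
    labels: np.ndarray | None = None,
    radius: int = 5,
    exclude: int | None = None,
) -> np.ndarray:
    """Median over a circular footprint restricted to same-label pixels.

    Parameters
    ----------
    image : 2D raster to filter.
    labels : 2D integer raster of region labels, or None for an unmasked
        circular median.  Footprint pixels whose label differs from the
        centre pixel's are ignored.
    radius : footprint radius in pixels; the footprint is truncated at the
        image borders (no padding values are invented).
    exclude : optional label value (e.g. background) whose pixels are both
        ignored in every footprint and passed through unchanged.

    A pixel whose footprint contains only itself returns its own value.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    h, w = image.shape
    r = int(radius)
    offs = disk_offsets(r)

    padded = np.full((h + 2 * r, w + 2 * r), np.nan)
    padded[r : r + h, r : r + w] = image

    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != image.shape:
            raise ValueError("labels must match the image shape")
        lab_pad = np.full((h + 2 * r, w + 2 * r), -1, dtype=np.int64)
        lab_pad[r : r + h, r : r + w] = labels

    stack = np.empty((offs.shape[0], h, w))
    for k, (dy, dx) in enumerate(offs):
        vals = padded[r + dy : r + dy + h, r + dx : r + dx + w]
        if labels is not None:
            neigh = lab_pad[r + dy : r + dy + h, r + dx : r + dx + w]
            vals = np.where(neigh == labels, vals, np.nan)
            if exclude is not None:
                vals = np.where(neigh == exclude, np.nan, vals)
        stack[k] = vals

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # all-NaN footprints (excluded labels) are handled explicitly below
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmedian(stack, axis=0)
    # Pixels with an empty footprint (e.g. excluded label) pass through.
    empty = np.isnan(out)
    if empty.any():
        out[empty] = image[empty]
    return out


def median_filter_disk(image: np.ndarray, radius: int = 5) -> np.ndarray:
    """Plain circular median filter with border-truncated footprint."""
    return masked_median_filter(image, labels=None, radius=radius)


def chunked_apply(
    op,
    arrays: list[np.ndarray] | tuple[np.ndarray, ...],
    chunk_shape: tuple[int, int],
    halo: int,
    footprint_radius: int | None = None,
) -> np.ndarray:
    """Apply a local operator tile by tile with overlapping halos.

    ``op`` maps one or more same-shape 2D arrays to one 2D array and must be
    local with influence radius <= ``halo`` (for the circular median filter
    that radius is the footprint radius).  The tiled result is identical to
    applying ``op`` to the whole image, because each tile is evaluated on
    its halo-padded neighbourhood (clipped at the true image borders, where
    the operator truncates anyway) and only the interior is kept.
    """
    arrays = [np.asarray(a) for a in arrays]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all input arrays must share one shape")
    if footprint_radius is not None and halo < footprint_radius:
        raise ValueError(
            f"halo ({halo}) is smaller than the operator footprint radius "
            f"({footprint_radius})"
        )
    ch, cw = int(chunk_shape[0]), int(chunk_shape[1])
    if ch < 1 or cw < 1:
        raise ValueError("chunk shape must be positive")

    h, w = shape
    out: np.ndarray | None = None
    for y0 in range(0, h, ch):
        for x0 in range(0, w, cw):
            y1, x1 = min(y0 + ch, h), min(x0 + cw, w)
            ys, xs = max(y0 - halo, 0), max(x0 - halo, 0)
            ye, xe = min(y1 + halo, h), min(x1 + halo, w)
            tiles = [a[ys:ye, xs:xe] for a in arrays]
            res = np.asarray(op(*tiles))
            if out is None:
                out = np.empty(shape, dtype=res.dtype)
            out[y0:y1, x0:x1] = res[y0 - ys : y1 - ys, x0 - xs : x1 - xs]
    assert out is not None
    return out
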