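"""Independent straight-line reference Canny for cross-checking the library.

Everything here is written as plain nested loops over pixels with no shared
code with ``folliseg.edge_ops`` — slow, but an unambiguous statement of the
conventions: symmetric border padding, correlation with the Sobel pair,
angle = atan2(dy, dx) quantised to four sectors, non-maximum suppression
keeping a pixel iff it is strictly greater than its lower-index directional
neighbour and at least as large as the higher-index one (out-of-bounds
neighbours count as 0), and 8-connected double-threshold hysteresis via
breadth-first search from strong pixels.
"""

import math
from collections import deque

REF_KX = [[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]
REF_KY = [[-1.0, -2.0, -1.0], [0.0, 0.0, 0.0], [1.0, 2.0, 1.0]]


def _reflect(i, n):
    # symmetric (half-sample) reflection for one pixel of padding
    if i < 0:
        return -i - 1
    if i >= n:
        return 2 * n - i - 1
    return i


def ref_sobel(img):
    h, w = len(img), len(img[0])
    dx = [[0.0] * w for _ in range(h)]
    dy = [[0.0] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            sx = 0.0
            sy = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    v = img[_reflect(i + di, h)][_reflect(j + dj, w)]
                    sx += REF_KX[di + 1][dj + 1] * v
                    sy += REF_KY[di + 1][dj + 1] * v
            dx[i][j] = sx
            dy[i][j] = sy
    return dx, dy


def ref_magnitude_angle(dx, dy):
    h, w = len(dx), len(dx[0])
    mag = [[0.0] * w for _ in range(h)]
    ang = [[0.0] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            mag[i][j] = math.hypot(dx[i][j], dy[i][j])
            ang[i][j] = math.atan2(dy[i][j], dx[i][j])
    return mag, ang


def ref_sector(angle):
    a = angle % math.pi
    return int(math.floor((a + math.pi / 8) / (math.pi / 4))) % 4


_SECTOR_OFFSETS = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}


def ref_nms(mag, ang):
    h, w = len(mag), len(mag[0])
    out = [[0.0] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            di, dj = _SECTOR_OFFSETS[ref_sector(ang[i][j])]
            pi_, pj = i - di, j - dj
            ni, nj = i + di, j + dj
            prev = mag[pi_][pj] if 0 <= pi_ < h and 0 <= pj < w else 0.0
            nxt = mag[ni][nj] if 0 <= ni < h and 0 <= nj < w else 0.0
            if mag[i][j] > prev and mag[i][j] >= nxt:
                out[i][j] = mag[i][j]
    return out


def ref_hysteresis(thin, low, high):
    h, w = len(thin), len(thin[0])
    edge = [[0] * w for _ in range(h)]
    seen = [[False] * w for _ in range(h)]
    queue = deque()
    for i in range(h):
        for j in range(w):
            if thin[i][j] >= high:
                edge[i][j] = 1
                seen[i][j] = True
                queue.append((i, j))
    while queue:
        i, j = queue.popleft()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and not seen[ni][nj] \
                        and thin[ni][nj] >= low:
                    edge[ni][nj] = 1
                    seen[ni][nj] = True
                    queue.append((ni, nj))
    return edge


def ref_canny(img, low, high):
    dx, dy = ref_sobel(img)
    mag, ang = ref_magnitude_angle(dx, dy)
    thin = ref_nms(mag, ang)
    return ref_hysteresis(thin, low, high)
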