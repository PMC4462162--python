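"""PLINK bed/bim/fam and GCTA binary-GRM codecs.

bed layout (variant-major): magic bytes 0x6c 0x1b then 0x01, followed by
ceil(N/4) bytes per SNP, two bits per individual, least-significant pair
first.  Two-bit codes: 00 = homozygous A1 (additive code 2), 10 = het (1),
11 = homozygous A2 (0), 01 = missing.

GCTA GRM triplet: <prefix>.grm.bin (float32 lower triangle including the
diagonal, row-major by individual), <prefix>.grm.N.bin (float32 per-pair
SNP counts, same order), <prefix>.grm.id (text, FID IID per line).
"""

from __future__ import annotations

import os

import numpy as np

from .greml import GRM, GenotypeMatrix

__all__ = [
    "read_plink_bed",
    "write_plink_bed",
    "read_grm_gcta",
    "write_grm_gcta",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# two-bit code -> additive count of A1 (3.0 is a sentinel for missing)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_MISSING_CODE = 0b01


def read_plink_bed(path_prefix: str) -> GenotypeMatrix:
    """Read <prefix>.bed/.bim/.fam into a GenotypeMatrix."""
    fam_path, bim_path, bed_path = (
        path_prefix + ext for ext in (".fam", ".bim", ".bed")
    )
    for p in (fam_path, bim_path, bed_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    fam = np.loadtxt(fam_path, dtype=str, ndmin=2)
    ids = np.array([f"{f[0]}_{f[1]}" if f[0] != f[1] else f[1] for f in fam])
    bim = np.loadtxt(bim_path, dtype=str, ndmin=2)
    n, m = ids.size, bim.shape[0]
    with open(bed_path, "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(
                f"bad bed magic bytes {magic!r}; expected variant-major PLINK bed"
            )
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if raw.size != bytes_per_snp * m:
        raise ValueError(
            f"truncated bed file: {raw.size} payload bytes, "
            f"expected {bytes_per_snp * m}"
        )
    raw = raw.reshape(m, bytes_per_snp)
    # expand each byte into 4 two-bit codes, LSB pair first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes2 = (raw[:, :, None] >> shifts) & 0b11  # (m, bytes, 4)
    codes2 = codes2.reshape(m, bytes_per_snp * 4)[:, :n]
    dosage = _CODE_TO_DOSAGE[codes2].T.astype(float)  # (n, m)
    return GenotypeMatrix(
        ids=ids,
        codes=np.ascontiguousarray(dosage),
        snp_ids=bim[:, 1].copy(),
        chrom=bim[:, 0].copy(),
        bp=bim[:, 3].astype(int),
        a1=bim[:, 4].copy(),
        a2=bim[:, 5].copy(),
    )


def write_plink_bed(g: GenotypeMatrix, path_prefix: str) -> None:
    """Write a GenotypeMatrix as variant-major <prefix>.bed/.bim/.fam."""
    n, m = g.codes.shape
    with open(path_prefix + ".fam", "w") as fh:
        for iid in g.ids:
            fh.write(f"{iid} {iid} 0 0 0 -9\n")
    with open(path_prefix + ".bim", "w") as fh:
        for j in range(m):
            fh.write(
                f"{g.chrom[j]}\t{g.snp_ids[j]}\t0\t{g.bp[j]}\t{g.a1[j]}\t{g.a2[j]}\n"
            )
    bytes_per_snp = (n + 3) // 4
    payload = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    codes = np.full((m, bytes_per_snp * 4), _MISSING_CODE, dtype=np.uint8)
    x = g.codes.T  # (m, n)
    two_bit = np.full(x.shape, _MISSING_CODE, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        two_bit[x == dosage] = code
    codes[:, :n] = two_bit
    for k, shift in enumerate((0, 2, 4, 6)):
        payload |= codes[:, k::4] << shift
    with open(path_prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(payload.tobytes())


def write_grm_gcta(grm: GRM, path_prefix: str) -> None:
    """Write the GCTA binary GRM triplet."""
    n = grm.n
    tril = np.tril_indices(n)
    with open(path_prefix + ".grm.bin", "wb") as fh:
        fh.write(grm.values[tril].astype("<f4").tobytes())
    with open(path_prefix + ".grm.N.bin", "wb") as fh:
        fh.write(grm.pair_n[tril].astype("<f4").tobytes())
    with open(path_prefix + ".grm.id", "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm_gcta(path_prefix: str) -> GRM:
    """Read a GCTA binary GRM triplet (values stored at single precision)."""
    with open(path_prefix + ".grm.id") as fh:
        rows = [line.split() for line in fh if line.strip()]
    if any(len(r) != 2 for r in rows):
        raise ValueError("grm.id lines must have exactly two fields (FID IID)")
    ids = np.array([r[1] for r in rows])
    n = ids.size
    n_tri = n * (n + 1) // 2
    vals_flat = np.fromfile(path_prefix + ".grm.bin", dtype="<f4")
    nobs_flat = np.fromfile(path_prefix + ".grm.N.bin", dtype="<f4")
    if vals_flat.size != n_tri or nobs_flat.size != n_tri:
        raise ValueError(
            f"GRM binary size mismatch: id file lists {n} individuals "
            f"({n_tri} pairs) but found {vals_flat.size} values"
        )
    values = np.zeros((n, n))
    pair_n = np.zeros((n, n))
    tril = np.tril_indices(n)
    values[tril] = vals_flat
    pair_n[tril] = nobs_flat
    values = values + np.tril(values, -1).T
    pair_n = pair_n + np.tril(pair_n, -1).T
    return GRM(ids=ids, values=values, pair_n=pair_n)
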