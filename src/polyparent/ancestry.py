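"""Ancestry-diagnostic alleles and chromosome painting of deduced gametes.

Wild accessions labelled with their (sub)species serve as references: an
allele carried by at least a fraction ``f_min`` of one group's references and
by at most ``f_out`` of all other references is diagnostic of that group.
A haplotype (typically the gamete deduced by haplotype subtraction) is then
painted window by window: within a window of consecutive diagnostic sites,
each group's ratio is the fraction of its diagnostic sites whose allele the
haplotype carries, and the window is labelled with the best-supported group
(or "unknown" when no group reaches ``min_ratio``). The resulting mosaic
reveals, e.g., *M. balbisiana*-introgressed segments in the unknown second
parent of an AAB cultivar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .local_scan import DeducedGamete
from .vcfio import GenotypeMatrix, MAX_PLOIDY

logger = logging.getLogger(__name__)

__all__ = [
    "DiagnosticSet",
    "AncestryMosaic",
    "build_diagnostic_set",
    "paint_haplotype",
    "mosaic_agreement",
    "label_windows_from_truth",
]

UNKNOWN = "unknown"


@dataclass
class DiagnosticSet:
    """Group-diagnostic alleles, indexed against the matrix they came from."""

    n_sites: int
    groups: list[str]
    site_idx: np.ndarray    # (n_entries,)
    allele: np.ndarray      # (n_entries,)
    group_id: np.ndarray    # (n_entries,) index into groups

    def per_group_counts(self) -> dict[str, int]:
        return {
            g: int((self.group_id == gi).sum()) for gi, g in enumerate(self.groups)
        }


@dataclass
class AncestryMosaic:
    haplotype_id: str
    chroms: np.ndarray       # per window
    starts: np.ndarray       # 1-based position of first diagnostic site
    ends: np.ndarray         # 1-based position of last diagnostic site
    centers: np.ndarray
    groups: list[str]
    ratios: np.ndarray       # (n_windows, n_groups), NaN when no site of g
    labels: np.ndarray       # object array of group names or "unknown"
    window_site_idx: list[np.ndarray]  # matrix site indices per window


def build_diagnostic_set(
    m: GenotypeMatrix,
    group_map: dict[str, str],
    reference_ids: list[str],
    f_min: float = 0.8,
    f_out: float = 0.0,
    expected_groups: list[str] | None = None,
) -> DiagnosticSet:
    """Identify ancestry-diagnostic alleles from labelled reference accessions.

    An allele is diagnostic of group g when carried by >= ``f_min`` of g's
    references (with a call) and <= ``f_out`` of all other references.
    With ``f_out=0`` a (site, allele) pair can match at most one group; any
    residual ambiguity is dropped. When ``expected_groups`` is given, each
    listed group must have at least one reference accession.
    """
    if not reference_ids:
        raise ValueError("at least one reference accession is required")
    groups = sorted({group_map[r] for r in reference_ids})
    for g in expected_groups or []:
        if g not in groups:
            raise ValueError(f"group {g!r} has no reference accession")
    carrier = {}  # group -> (n_sites, 4) carrier counts; total likewise
    called = {}
    for r in reference_ids:
        g = group_map[r]
        pres = m.allele_presence(r)
        has_call = ~m.missing_mask(r)
        if g not in carrier:
            carrier[g] = np.zeros((m.n_sites, MAX_PLOIDY), dtype=np.int32)
            called[g] = np.zeros(m.n_sites, dtype=np.int32)
        carrier[g] += pres.astype(np.int32)
        called[g] += has_call.astype(np.int32)
    site_idx, allele, group_id = [], [], []
    assigned = np.full((m.n_sites, MAX_PLOIDY), -1, dtype=np.int32)
    for gi, g in enumerate(groups):
        with np.errstate(invalid="ignore", divide="ignore"):
            freq_in = carrier[g] / np.maximum(called[g][:, None], 1)
        out_carrier = np.zeros((m.n_sites, MAX_PLOIDY), dtype=np.int32)
        out_called = np.zeros(m.n_sites, dtype=np.int32)
        for h in groups:
            if h != g:
                out_carrier += carrier[h]
                out_called += called[h]
        freq_out = out_carrier / np.maximum(out_called[:, None], 1)
        hit = (called[g][:, None] > 0) & (freq_in >= f_min) & (freq_out <= f_out)
        s, a = np.nonzero(hit)
        for si, ai in zip(s, a):
            if assigned[si, ai] >= 0:
                assigned[si, ai] = -2  # ambiguous: claimed by two groups
            else:
                assigned[si, ai] = gi
    s, a = np.nonzero(assigned >= 0)
    order = np.lexsort((a, s))
    ds = DiagnosticSet(
        n_sites=m.n_sites,
        groups=groups,
        site_idx=s[order].astype(np.int64),
        allele=a[order].astype(np.int64),
        group_id=assigned[s[order], a[order]].astype(np.int64),
    )
    logger.info("build_diagnostic_set: %s", ds.per_group_counts())
    return ds


def _haplotype_presence(
    m: GenotypeMatrix, h: "DeducedGamete | np.ndarray"
) -> tuple[np.ndarray, np.ndarray, str]:
    """(n_sites, 4) carries-allele matrix, per-site usable mask, and an id."""
    if isinstance(h, DeducedGamete):
        if len(h.pos) != m.n_sites:
            raise ValueError("deduced gamete and matrix site grids differ")
        res = h.residual
        pres = np.stack([(res == a).any(axis=1) for a in range(MAX_PLOIDY)], axis=1)
        usable = ~(h.conflict | h.missing)
        return pres, usable, f"{h.child}-minus-{h.parent}"
    arr = np.asarray(h)
    if arr.shape[0] != m.n_sites:
        raise ValueError("haplotype length does not match the matrix site grid")
    pres = np.stack([arr == a for a in range(MAX_PLOIDY)], axis=1)
    usable = arr >= 0
    return pres, usable, "haplotype"


def paint_haplotype(
    m: GenotypeMatrix,
    h: "DeducedGamete | np.ndarray",
    d: DiagnosticSet,
    window_sites: int = 100,
    min_ratio: float = 0.5,
) -> AncestryMosaic:
    """Window-wise ancestry assignment of one haplotype.

    Windows tile the consecutive *diagnostic* sites of each chromosome in
    blocks of ``window_sites`` (a trailing remainder joins the last block).
    CONFLICT/missing sites are skipped. A window is labelled with the group of
    highest ratio if that ratio reaches ``min_ratio``, else "unknown".
    """
    if d.n_sites != m.n_sites:
        raise ValueError("diagnostic set was built from a different matrix")
    pres, usable, hap_id = _haplotype_presence(m, h)
    n_groups = len(d.groups)
    # per diagnostic entry: does the haplotype carry the diagnostic allele?
    carried = pres[d.site_idx, d.allele]
    entry_usable = usable[d.site_idx]
    chroms_w, starts, ends, centers = [], [], [], []
    ratios_w, labels, win_sites = [], [], []
    for chrom, idx in m.chrom_site_index().items():
        lo, hi = idx[0], idx[-1]
        e_mask = (d.site_idx >= lo) & (d.site_idx <= hi)
        entries = np.flatnonzero(e_mask)
        if len(entries) == 0:
            continue
        # windows over distinct diagnostic sites, in site order
        sites_here = np.unique(d.site_idx[entries])
        n_win = max(len(sites_here) // window_sites, 1)
        for w in range(n_win):
            s_lo = w * window_sites
            s_hi = len(sites_here) if w == n_win - 1 else (w + 1) * window_sites
            wsites = sites_here[s_lo:s_hi]
            in_w = entries[np.isin(d.site_idx[entries], wsites)]
            ratio = np.full(n_groups, np.nan)
            for gi in range(n_groups):
                sel = in_w[(d.group_id[in_w] == gi) & entry_usable[in_w]]
                if len(sel):
                    ratio[gi] = carried[sel].mean()
            if np.all(np.isnan(ratio)):
                label = UNKNOWN
            else:
                gi = int(np.nanargmax(ratio))
                label = d.groups[gi] if ratio[gi] >= min_ratio else UNKNOWN
            chroms_w.append(chrom)
            starts.append(int(m.pos[wsites[0]]))
            ends.append(int(m.pos[wsites[-1]]))
            centers.append(int(m.pos[wsites[len(wsites) // 2]]))
            ratios_w.append(ratio)
            labels.append(label)
            win_sites.append(wsites)
    return AncestryMosaic(
        haplotype_id=hap_id,
        chroms=np.array(chroms_w, dtype=object),
        starts=np.array(starts), ends=np.array(ends), centers=np.array(centers),
        groups=list(d.groups),
        ratios=np.array(ratios_w) if ratios_w else np.empty((0, n_groups)),
        labels=np.array(labels, dtype=object),
        window_site_idx=win_sites,
    )


def mosaic_agreement(a: AncestryMosaic, b: AncestryMosaic) -> float:
    """Fraction of windows with identical labels; windows labelled "unknown"
    in either mosaic are excluded from the denominator."""
    if len(a.labels) != len(b.labels) or not np.array_equal(a.centers, b.centers):
        raise ValueError("mosaics are on different window grids")
    informative = (a.labels != UNKNOWN) & (b.labels != UNKNOWN)
    if not informative.any():
        return float("nan")
    return float((a.labels[informative] == b.labels[informative]).mean())


def label_windows_from_truth(
    mosaic: AncestryMosaic,
    truth_ancestry: np.ndarray,
    ancestry_names: tuple[str, ...],
    d: DiagnosticSet | None = None,
    min_ratio: float = 0.5,
) -> AncestryMosaic:
    """Project a per-site true ancestry vector onto a painted mosaic's window
    grid, giving a truth mosaic directly comparable with
    :func:`mosaic_agreement`.

    When a diagnostic set is supplied, each window is labelled by the same
    per-group ratio the painter uses, evaluated on the true ancestries (the
    painter's noise-free expectation); otherwise by the majority ancestry of
    the window's sites.
    """
    name_to_idx = {n: i for i, n in enumerate(ancestry_names)}
    labels = []
    for w, wsites in enumerate(mosaic.window_site_idx):
        if d is not None:
            in_w = np.flatnonzero(np.isin(d.site_idx, wsites))
            ratio = np.full(len(mosaic.groups), np.nan)
            for gi, g in enumerate(mosaic.groups):
                sel = in_w[d.group_id[in_w] == gi]
                if len(sel) and g in name_to_idx:
                    ratio[gi] = np.mean(
                        truth_ancestry[d.site_idx[sel]] == name_to_idx[g]
                    )
            if np.all(np.isnan(ratio)):
                labels.append(UNKNOWN)
            else:
                gi = int(np.nanargmax(ratio))
                labels.append(
                    mosaic.groups[gi] if ratio[gi] >= min_ratio else UNKNOWN
                )
            continue
        anc = truth_ancestry[wsites]
        anc = anc[anc >= 0]
        if len(anc) == 0:
            labels.append(UNKNOWN)
            continue
        vals, counts = np.unique(anc, return_counts=True)
        labels.append(ancestry_names[int(vals[np.argmax(counts)])])
    return AncestryMosaic(
        haplotype_id=mosaic.haplotype_id + "-truth",
        chroms=mosaic.chroms.copy(), starts=mosaic.starts.copy(),
        ends=mosaic.ends.copy(), centers=mosaic.centers.copy(),
        groups=list(mosaic.groups),
        ratios=np.full_like(mosaic.ratios, np.nan),
        labels=np.array(labels, dtype=object),
        window_site_idx=list(mosaic.window_site_idx),
    )
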