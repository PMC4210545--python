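"""Independent oracles used by the test suite.

These deliberately avoid the implementation's code paths: trimming is done
by exhaustive enumeration, chain mapping by expanding a per-base lookup
table straight from the chain text, coding effects by rebuilding the
mutated chromosome and re-extracting/translating the CDS.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from Bio.Seq import Seq


def brute_force_trim(
    chrom: str, pos: int, ref: str, alt: str
) -> Tuple[str, int, str, str]:
    """Enumerate every prefix/suffix trim preserving the allele change and
    return the minimal representation (smallest total allele length, ties
    broken toward the smallest position)."""
    best = None
    for p in range(0, min(len(ref), len(alt))):
        if ref[:p] != alt[:p]:
            break
        for s in range(0, min(len(ref), len(alt)) - p):
            if s and ref[-s:] != alt[-s:]:
                break
            new_ref = ref[p: len(ref) - s]
            new_alt = alt[p: len(alt) - s]
            if not new_ref or not new_alt or new_ref == new_alt:
                continue
            cand = (len(new_ref) + len(new_alt), pos + p, new_ref, new_alt)
            if best is None or cand[:2] < best[:2]:
                best = cand
    assert best is not None
    return (chrom, best[1], best[2], best[3])


def expand_chain_map(chain_text: str) -> Dict[Tuple[str, int], Tuple[str, int]]:
    """Per-base source->target map (1-based) from raw chain text."""
    mapping: Dict[Tuple[str, int], Tuple[str, int]] = {}
    header = None
    cur_s = cur_t = 0
    for raw in chain_text.splitlines():
        line = raw.strip()
        if not line:
            header = None
            continue
        if line.startswith("chain"):
            f = line.split()
            header = {"s_chrom": f[2], "t_chrom": f[7]}
            cur_s, cur_t = int(f[5]), int(f[10])
            continue
        if header is None:
            continue
        nums = [int(x) for x in line.split()]
        size = nums[0]
        ds = nums[1] if len(nums) == 3 else 0
        dt = nums[2] if len(nums) == 3 else 0
        for i in range(size):
            mapping[(header["s_chrom"], cur_s + i + 1)] = (
                header["t_chrom"], cur_t + i + 1
            )
        cur_s += size + ds
        cur_t += size + dt
    return mapping


def rebuild_and_translate(
    contig: str,
    coding_segments: List[Tuple[int, int]],
    strand: str,
    pos: int,
    ref: str,
    alt: str,
) -> Tuple[str, str]:
    """(protein_before, protein_after) by editing the chromosome and
    re-extracting the spliced CDS.

    The edit must lie entirely inside one coding segment; segments after it
    shift by the length difference.
    """
    assert contig[pos - 1: pos - 1 + len(ref)] == ref, "ref mismatch"
    mutated = contig[: pos - 1] + alt + contig[pos - 1 + len(ref):]
    shift = len(alt) - len(ref)
    edit_end = pos + len(ref) - 1

    def extract(seq: str, shifted: bool) -> str:
        parts = []
        for s, e in coding_segments:
            if not shifted:
                parts.append(seq[s - 1: e])
            elif e < pos:
                parts.append(seq[s - 1: e])
            elif s > edit_end:
                parts.append(seq[s - 1 + shift: e + shift])
            else:
                assert s <= pos and edit_end <= e, "edit crosses a segment"
                parts.append(seq[s - 1: e + shift])
        cds = "".join(parts)
        if strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    before = extract(contig, shifted=False)
    after = extract(mutated, shifted=True)
    prot_before = str(Seq(before[: len(before) - len(before) % 3]).translate())
    prot_after = str(Seq(after[: len(after) - len(after) % 3]).translate())
    return prot_before, prot_after


def oracle_effect(
    contig: str,
    coding_segments: List[Tuple[int, int]],
    strand: str,
    pos: int,
    ref: str,
    alt: str,
) -> str:
    """Coding-effect label from full rebuild-and-translate comparison."""
    if len(ref) != len(alt):
        return (
            "frameshift"
            if abs(len(ref) - len(alt)) % 3 != 0
            else "inframe"
        )
    before, after = rebuild_and_translate(
        contig, coding_segments, strand, pos, ref, alt
    )
    if before == after:
        return "synonymous"
    for a, b in zip(before, after):
        if a != b:
            if b == "*":
                return "stopgain"
            if a == "*":
                return "stoploss"
            return "missense"
    return "synonymous"


def write_trio_store(store, vcf_text: str, tmp_path, keep_homref=True):
    """Register the trio pedigree and import all three sample columns."""
    from varbank import fixtures as fx, import_vcf, load_pedigree

    pid = store.create_project("trio")
    load_pedigree(store, fx.trio_pedigree(), pid, fx.trio_sidecar())
    vcf_path = tmp_path / "trio.vcf"
    vcf_path.write_text(vcf_text)
    for sample in fx.TRIO_SAMPLES:
        import_vcf(
            store, sample, vcf_path, "hg19",
            sample_column=sample, keep_homref=keep_homref,
        )
    return store


def variant_keys(variants) -> list:
    return sorted((v.chrom, v.pos, v.ref, v.alt) for v in variants)
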