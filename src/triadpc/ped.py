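"""Linkage-format (PED/MAP) input and the end-to-end test pipeline.

A PED row is ``family individual father mother sex phenotype`` followed by
two allele columns per SNP ("0" = missing allele); the companion MAP file
lists ``chromosome snp_id genetic_distance position`` per SNP.  Trios are
assembled from the pedigree pointers: every affected child (phenotype 2)
whose father and mother both appear in the same family becomes one trio.
Positions are informational only — the tests never use them.

Allele pairs are collapsed to counts of a per-SNP counted allele.  By
default the counted allele is the minor allele in the parental pool (ties
broken lexicographically); the choice is inconsequential for inference
because recoding c -> 2 - c for all three members negates X and Y and
leaves PC, Z^2 and the permutation p-value unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .permutation import PermutationPlan, STATISTICS, permute_all_stats, permute_stat
from .trio_stats import MISSING, TrioGenotypes, check_mendelian

__all__ = ["read_ped", "write_ped", "run_test", "PedigreeError"]

log = logging.getLogger(__name__)


class PedigreeError(ValueError):
    """Malformed pedigree input."""


@dataclass
class _Individual:
    iid: str
    father: str
    mother: str
    phenotype: str
    alleles: list[tuple[str, str]]


def _parse_ped(ped_path) -> dict[str, dict[str, _Individual]]:
    families: dict[str, dict[str, _Individual]] = {}
    n_snps = None
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 8 or (len(tokens) - 6) % 2:
                raise PedigreeError(
                    f"{ped_path}:{lineno}: expected 6 pedigree columns plus "
                    f"2 allele columns per SNP, got {len(tokens)} fields")
            if n_snps is None:
                n_snps = (len(tokens) - 6) // 2
            elif (len(tokens) - 6) // 2 != n_snps:
                raise PedigreeError(
                    f"{ped_path}:{lineno}: inconsistent SNP count")
            fid, iid, pat, mat, _sex, pheno = tokens[:6]
            alleles = list(zip(tokens[6::2], tokens[7::2]))
            families.setdefault(fid, {})[iid] = _Individual(
                iid=iid, father=pat, mother=mat, phenotype=pheno,
                alleles=alleles)
    if n_snps is None:
        raise PedigreeError(f"{ped_path}: empty PED file")
    return families


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 4:
                raise PedigreeError(
                    f"{map_path}:{lineno}: expected 4 columns "
                    "(chrom, snp_id, cM, position)")
            rows.append({"chrom": tokens[0], "snp_id": tokens[1],
                         "cm": tokens[2], "pos": int(tokens[3])})
    return pd.DataFrame(rows)


def _counted_allele(mothers, fathers, snp: int) -> str | None:
    """Minor allele among the parents at one SNP; ties lexicographic."""
    counts: dict[str, int] = {}
    for ind in list(mothers) + list(fathers):
        for a in ind.alleles[snp]:
            if a != "0":
                counts[a] = counts.get(a, 0) + 1
    if not counts:
        return None
    if len(counts) > 2:
        raise PedigreeError(f"SNP {snp}: more than two alleles {sorted(counts)}")
    return min(counts, key=lambda a: (counts[a], a))


def _dose(ind: _Individual, snp: int, counted: str | None) -> int:
    a, b = ind.alleles[snp]
    if a == "0" or b == "0" or counted is None:
        return MISSING
    return int(a == counted) + int(b == counted)


def read_ped(ped_path, map_path, counted_alleles=None,
             mendelian_policy: str = "drop-cell") -> TrioGenotypes:
    """Assemble case-parent trios from PED/MAP files.

    Parameters
    ----------
    counted_alleles : sequence of per-SNP allele symbols, optional.  When
        omitted, the minor allele in the parental pool is counted.
    mendelian_policy : what to do with cells where the child's genotype is
        impossible given the parents: "drop-cell" (default) marks the cell
        missing, "drop-trio" removes the trio, "error" raises.
    """
    if mendelian_policy not in ("drop-cell", "drop-trio", "error"):
        raise ValueError("mendelian_policy must be drop-cell/drop-trio/error")
    families = _parse_ped(ped_path)
    snp_table = _read_map(map_path)
    n_snps = next(iter(next(iter(families.values())).values())).alleles
    n_snps = len(n_snps)
    if len(snp_table) != n_snps:
        raise PedigreeError(
            f"MAP lists {len(snp_table)} SNPs but PED carries {n_snps}")

    trios: list[tuple[_Individual, _Individual, _Individual]] = []
    n_dropped = 0
    for fid, members in families.items():
        affected = [ind for ind in members.values() if ind.phenotype == "2"
                    and (ind.father != "0" or ind.mother != "0")]
        used = set()
        for child in affected:
            father = members.get(child.father)
            mother = members.get(child.mother)
            if father is None or mother is None:
                log.warning("family %s: affected child %s lacks a genotyped "
                            "parent; trio skipped", fid, child.iid)
                n_dropped += 1
                continue
            trios.append((mother, father, child))
            used.update({child.iid, father.iid, mother.iid})
        if len([c for c in affected]) > 1:
            log.warning("family %s contributes %d affected children; the "
                        "trios are not independent", fid, len(affected))
    if not trios:
        raise PedigreeError("no complete case-parent trio found")

    mothers = [t[0] for t in trios]
    fathers = [t[1] for t in trios]
    if counted_alleles is None:
        counted = [_counted_allele(mothers, fathers, s) for s in range(n_snps)]
    else:
        counted = [str(a) for a in counted_alleles]
        if len(counted) != n_snps:
            raise ValueError("counted_alleles length must equal SNP count")

    M = np.array([[_dose(m, s, counted[s]) for s in range(n_snps)]
                  for m in mothers])
    F = np.array([[_dose(f, s, counted[s]) for s in range(n_snps)]
                  for f in fathers])
    C = np.array([[_dose(t[2], s, counted[s]) for s in range(n_snps)]
                  for t in trios])
    result = TrioGenotypes(M=M, F=F, C=C,
                           snp_ids=tuple(snp_table["snp_id"]))
    violations = check_mendelian(result)
    if violations:
        if mendelian_policy == "error":
            raise PedigreeError(f"{len(violations)} Mendelian-inconsistent "
                                f"cells, first at (trio, locus) {violations[0]}")
        log.warning("%d Mendelian-inconsistent cells (%s)", len(violations),
                    mendelian_policy)
        if mendelian_policy == "drop-cell":
            for i, l in violations:
                M[i, l] = F[i, l] = C[i, l] = MISSING
            result = TrioGenotypes(M=M, F=F, C=C, snp_ids=result.snp_ids)
        else:  # drop-trio
            bad = sorted({i for i, _ in violations})
            keep = np.ones(len(trios), dtype=bool)
            keep[bad] = False
            if not keep.any():
                raise PedigreeError("all trios Mendelian-inconsistent")
            result = TrioGenotypes(M=M[keep], F=F[keep], C=C[keep],
                                   snp_ids=result.snp_ids)
    return result


def write_ped(trios: TrioGenotypes, ped_path, map_path,
              positions=None, chrom: str = "1") -> None:
    """Write trios as PED/MAP; the counted allele is written as "2".

    Counts map to allele pairs 0 -> "1 1", 1 -> "1 2", 2 -> "2 2",
    missing -> "0 0".  Parents have phenotype 1, the child 2.
    """
    n, q = trios.n_trios, trios.n_loci
    ids = trios.snp_ids or tuple(f"snp{l + 1}" for l in range(q))
    if positions is None:
        positions = [1000 * (l + 1) for l in range(q)]

    def pair(c):
        return {0: "1 1", 1: "1 2", 2: "2 2"}.get(int(c), "0 0")

    with open(ped_path, "w") as fh:
        for i in range(n):
            fam = f"fam{i + 1}"
            rows = [
                (f"{fam}", "1", "0", "0", "1", "1", trios.F[i]),
                (f"{fam}", "2", "0", "0", "2", "1", trios.M[i]),
                (f"{fam}", "3", "1", "2", "0", "2", trios.C[i]),
            ]
            for fid, iid, pat, mat, sex, pheno, geno in rows:
                alleles = " ".join(pair(geno[l]) for l in range(q))
                fh.write(f"{fid} {iid} {pat} {mat} {sex} {pheno} {alleles}\n")
    with open(map_path, "w") as fh:
        for l in range(q):
            fh.write(f"{chrom} {ids[l]} 0 {int(positions[l])}\n")


def run_test(trios: TrioGenotypes, statistic: str = "all",
             n_permutations: int = 1000, seed: int | None = None,
             add_one_correction: bool = False,
             per_locus_pvalues: bool = False,
             out_dir=None) -> dict:
    """Full pipeline: difference scores, scan statistic(s), permutation p.

    Returns a report dict; when ``out_dir`` is given also writes
    ``per_locus.tsv`` and ``summary.json`` there.
    """
    from .trio_stats import compute_diff_vectors  # local to avoid cycle noise

    diffs = compute_diff_vectors(trios)
    plan = PermutationPlan.generate(n_permutations, trios.n_trios, seed)
    if statistic == "all":
        wanted = STATISTICS
        results = permute_all_stats(diffs, plan,
                                    add_one_correction=add_one_correction)
    elif statistic in STATISTICS:
        wanted = (statistic,)
        results = {statistic: permute_stat(diffs, statistic, plan,
                                           add_one_correction)}
    else:
        raise ValueError(f"statistic must be 'all' or one of {STATISTICS}")

    ids = trios.snp_ids or tuple(f"snp{l + 1}" for l in range(trios.n_loci))
    first = results[wanted[0]]
    table = pd.DataFrame({"snp_id": ids,
                          "n_complete": first.n_complete})
    col_by_stat = {"max_pc": "pc", "max_z2_assoc": "z2_assoc",
                   "max_z2_maternal": "z2_maternal"}
    for name in wanted:
        table[col_by_stat[name]] = results[name].per_locus
    if per_locus_pvalues:
        # per-locus permutation p-values: share the same swaps, compare each
        # locus's statistic to its own permutation distribution
        from .trio_stats import _masked_scores, _pc_matrix, _z2_matrix
        x, y, w = _masked_scores(diffs)
        sx, sy = plan.signs()
        mats = {"max_pc": _pc_matrix(x, y, w, sx, sy)[0],
                "max_z2_assoc": _z2_matrix(x, w, sx)[0],
                "max_z2_maternal": _z2_matrix(y, w, sy)[0]}
        for name in wanted:
            obs = results[name].per_locus
            with np.errstate(invalid="ignore"):
                p_loc = (mats[name] > obs[None, :]).mean(axis=0)
            table[col_by_stat[name] + "_p"] = np.where(
                np.isnan(obs), np.nan, p_loc)

    summary = {
        "n_trios": trios.n_trios,
        "n_loci": trios.n_loci,
        "n_permutations": n_permutations,
        "seed": seed,
        "add_one_correction": add_one_correction,
        "statistics": {name: {
            "max_stat": results[name].max_stat,
            "argmax_snp": ids[results[name].argmax_locus],
            "p_value": results[name].p_value,
        } for name in wanted},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "per_locus.tsv", sep="\t", index=False,
                     float_format="%.6g")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return {"summary": summary, "per_locus": table, "results": results}
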