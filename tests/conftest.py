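import textwrap

import pytest

from ptmburden.catalog import ProteinInfo, PTMSite, build_partition


@pytest.fixture
def write_tsv(tmp_path):
    """Write a small TSV from header + rows; returns the path."""

    def _write(name, header, rows):
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def site_catalog(write_tsv):
    def _make(rows, name="sites.tsv"):
        return write_tsv(
            name, ["accession", "position", "residue", "ptm_type", "evidence"], rows
        )

    return _make


@pytest.fixture
def mutation_table(write_tsv):
    def _make(rows, name="mutations.tsv"):
        return write_tsv(
            name,
            ["sample_id", "accession", "position", "ref_aa", "alt_aa", "consequence"],
            rows,
        )

    return _make


@pytest.fixture
def fasta_file(tmp_path):
    def _make(records, name="proteome.fasta"):
        path = tmp_path / name
        chunks = []
        for acc, seq in records:
            chunks.append(f">{acc}\n{seq}")
        path.write_text("\n".join(chunks) + "\n")
        return path

    return _make


@pytest.fixture
def simple_partition():
    """Protein of 100 residues, one phospho-site at position 10, window 7."""
    info = ProteinInfo("P1", 100)
    sites = [PTMSite("P1", 10, "Phosphorylation")]
    return build_partition(info, sites, window=7)


@pytest.fixture
def minimal_vcf(tmp_path):
    """Uncompressed VCF carrying the protein annotation INFO key."""

    def _make(body_lines, ann_key="PTM_ANN", name="muts.vcf"):
        header = textwrap.dedent(
            f"""\
            ##fileformat=VCFv4.2
            ##contig=<ID=chr1,length=248956422>
            ##INFO=<ID={ann_key},Number=.,Type=String,Description="accession|position|ref_aa|alt_aa|consequence per ALT">
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
            """
        )
        path = tmp_path / name
        path.write_text(header + "\n".join(body_lines) + "\n")
        return path

    return _make
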