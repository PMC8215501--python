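import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=END,Number=1,Type=Integer,Description="End">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise">
##INFO=<ID=szCount,Number=1,Type=Integer,Description="Support">
##INFO=<ID=coverage,Number=1,Type=Integer,Description="Coverage">
##FILTER=<ID=LongReadHomRef,Description="Hom ref">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##contig=<ID=1,length=100000000>
##contig=<ID=2,length=100000000>
##contig=<ID=3,length=100000000>
##contig=<ID=chr3,length=100000000>
"""


@pytest.fixture
def write_vcf(tmp_path):
    """Write a VCF from body lines (tab-joined tuples or raw strings)."""

    def _write(body_lines, name="test.vcf", with_sample=False, extra_header=""):
        header = VCF_HEADER + extra_header
        if with_sample:
            header += ('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
                       '##FORMAT=<ID=szCount,Number=1,Type=Integer,Description="S">\n'
                       '##FORMAT=<ID=coverage,Number=1,Type=Integer,Description="C">\n')
            header += "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n"
        else:
            header += "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        lines = ["\t".join(map(str, l)) if not isinstance(l, str) else l
                 for l in body_lines]
        path = tmp_path / name
        path.write_text(header + "".join(line + "\n" for line in lines))
        return str(path)

    return _write
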