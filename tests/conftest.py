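import os

import pytest

from ratchetsplice.genome_io import SequenceStore, load_annotation
from ratchetsplice.motif_scoring import build_pwms
from ratchetsplice.synthetic_data import simulate_study

# Three transcripts over one gene: t1 has two exons (one intron), t2 shares
# t1's donor but uses a farther acceptor, t3 is single-exon.
TOY_GFF3 = """\
##gff-version 3
chr1\t.\tgene\t1\t2000\t.\t+\t.\tID=gA
chr1\t.\tmRNA\t1\t2000\t.\t+\t.\tID=gA.t1;Parent=gA
chr1\t.\texon\t101\t200\t.\t+\t.\tParent=gA.t1
chr1\t.\texon\t301\t400\t.\t+\t.\tParent=gA.t1
chr1\t.\tmRNA\t1\t2000\t.\t+\t.\tID=gA.t2;Parent=gA
chr1\t.\texon\t101\t200\t.\t+\t.\tParent=gA.t2
chr1\t.\texon\t501\t600\t.\t+\t.\tParent=gA.t2
chr1\t.\tmRNA\t1\t2000\t.\t+\t.\tID=gA.t3;Parent=gA
chr1\t.\texon\t701\t900\t.\t+\t.\tParent=gA.t3
"""


@pytest.fixture(scope="session")
def toy_annotation():
    return load_annotation(TOY_GFF3)


@pytest.fixture(scope="session")
def study():
    """Small synthetic study shared across unit tests (2 recursive, 2 decoy)."""
    return simulate_study(n_recursive=2, n_decoy=2, seed=42)


@pytest.fixture(scope="session")
def study_env(study, tmp_path_factory):
    """(annotation, genome store, sam path, pwm) derived from the study."""
    d = tmp_path_factory.mktemp("study")
    sam_path = os.path.join(d, "reads.sam")
    with open(sam_path, "w") as fh:
        fh.write(study.sam_text)
    annotation = load_annotation(study.gff3())
    genome = SequenceStore(study.genome)
    pwm = build_pwms(annotation, genome)
    return annotation, genome, sam_path, pwm
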