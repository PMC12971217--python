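"""Shared fixtures and exam-building helpers."""

import pytest

from nasodx.grading import MISSING, ExamGrading, SideGrades


def make_exam(participant="P1", rater="R1",
              inv_pre=(0.0, 0.0), inv_post=(0.0, 0.0),
              it_pre=(1.0, 1.0), it_post=(1.0, 1.0),
              dns_pre=(0.0, 0.0), dns_post=(0.0, 0.0),
              polyp_pre=(0.0, 0.0), polyp_post=None):
    """Build an ExamGrading from per-scale (left, right) tuples.

    Defaults are a clean control pattern; polyp_post mirrors polyp_pre
    unless given.
    """
    if polyp_post is None:
        polyp_post = polyp_pre

    def side(idx, tp):
        if tp == "pre":
            return SideGrades(inv=inv_pre[idx], it=it_pre[idx],
                              dns=dns_pre[idx], polyp=polyp_pre[idx])
        return SideGrades(inv=inv_post[idx], it=it_post[idx],
                          dns=dns_post[idx], polyp=polyp_post[idx])

    return ExamGrading(
        participant_id=participant, rater_id=rater,
        pre_left=side(0, "pre"), pre_right=side(1, "pre"),
        post_left=side(0, "post"), post_right=side(1, "post"),
    )


@pytest.fixture
def control_exam():
    return make_exam()


@pytest.fixture
def crswnp_exam():
    """Bilateral polyps, everything else in the control range."""
    return make_exam(polyp_pre=(2.0, 1.0))


@pytest.fixture
def ar_exam():
    """Bilateral >=35% IT response plus bilateral INV >=1 pre only."""
    return make_exam(it_pre=(4.0, 3.0), it_post=(2.0, 1.0),
                     inv_pre=(1.0, 2.0), inv_post=(0.0, 2.0 / 3.0))


@pytest.fixture
def dns_exam():
    """Post-decongestant septal asymmetry only."""
    return make_exam(dns_pre=(2.0, 0.0), dns_post=(2.0, 0.0))


@pytest.fixture
def crssnp_exam():
    """Bilateral INV >=1 pre and post, no decongestant response."""
    return make_exam(inv_pre=(1.0, 1.0), inv_post=(2.0, 1.0))


MISSING_EXAM = ExamGrading(participant_id="PM", rater_id="R1")
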