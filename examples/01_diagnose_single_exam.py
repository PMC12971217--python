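"""Diagnose a single graded exam with the five-question rule engine.

Builds one participant's grading by hand — bilateral turbinates that
shrink by half after decongestant plus an obstructed valve before
decongestant only — and walks it through the question vector and the
decision table.
"""

from nasodx import (ExamGrading, SideGrades, diagnose, evaluate_questions,
                    format_diagnosis_set)

exam = ExamGrading(
    participant_id="demo-1", rater_id="consultant-1",
    # left / right before decongestant: big turbinates, valve blocked
    pre_left=SideGrades(inv=1.0, it=4.0, dns=0.0, polyp=0.0),
    pre_right=SideGrades(inv=2.0, it=3.0, dns=0.0, polyp=0.0),
    # ten minutes after xylometazoline: turbinates halved, valve open
    post_left=SideGrades(inv=0.0, it=2.0, dns=0.0, polyp=0.0),
    post_right=SideGrades(inv=2.0 / 3.0, it=1.0, dns=0.0, polyp=0.0),
)

qv = evaluate_questions(exam)
print("question vector:", tuple(qv))
print("diagnosis:      ", format_diagnosis_set(diagnose(exam)))
print()
print("Q2 is true (both turbinates shrank >=35%) and Q4 is true (valve")
print("grade >=1 on both sides pre-decongestant, with 'maybe 1' = 2/3")
print("counting as open post-decongestant), which the table reads as")
print("allergic rhinitis: reversible congestion behind an obstructed valve.")
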