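q1,q2,q3,q4,q5,diagnosis
T,T,T,T,T,AR+CRSwNP+DNS
T,T,T,T,F,AR+CRSwNP+DNS
T,T,T,F,T,CRSwNP+DNS
T,T,T,F,F,CRSwNP+DNS
T,T,F,T,T,AR+CRSwNP
T,T,F,T,F,AR+CRSwNP
T,T,F,F,T,CRSwNP
T,T,F,F,F,CRSwNP
T,F,T,T,T,CRSwNP+DNS
T,F,T,T,F,CRSwNP+DNS
T,F,T,F,T,CRSwNP+DNS
T,F,T,F,F,CRSwNP+DNS
T,F,F,T,T,CRSwNP
T,F,F,T,F,CRSwNP
T,F,F,F,T,CRSwNP
T,F,F,F,F,CRSwNP
F,T,T,T,T,AR+CRSsNP+DNS
F,T,T,T,F,AR+DNS
F,T,T,F,T,DNS
F,T,T,F,F,DNS
F,T,F,T,T,AR+CRSsNP
F,T,F,T,F,AR
F,T,F,F,T,Controls
F,T,F,F,F,Controls
F,F,T,T,T,CRSsNP+DNS
F,F,T,T,F,CRSsNP+DNS
F,F,T,F,T,DNS
F,F,T,F,F,DNS
F,F,F,T,T,CRSsNP
F,F,F,T,F,CRSsNP
F,F,F,F,T,Controls
F,F,F,F,F,Controls
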