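// A. thaliana root stem-cell-niche Boolean GRN (nine genes).
// SHR and AUXINS have no regulators of their own: written as
// self-sustaining so their value persists.
PLT := ARF;
AUXINS := AUXINS;
IAA := ~ AUXINS;
ARF := ~ IAA;
SHR := SHR;
SCR := SHR & SCR & (JKD | ~ MGP);
JKD := SHR & SCR;
MGP := SHR & SCR & ~ WOX;
WOX := ARF & SHR & SCR & (~ MGP | WOX);
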