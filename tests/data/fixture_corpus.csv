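karyotype,expected,note
"57,XX,+X,+4,+6,+10,+14,+17,+18,+21,+21[12]/46,XX[8]",D-GR,classic HeH with +17+18 and a normal line
"46,XY[20]",not_heh,normal male karyotype
"52,XY,+5,+8,+10,+17,inc[10]",P-GR,incomplete karyotype; 17 gained certain; 18/20 uncertain
"54,XY,t(9;22)(q34;q11),+4,+6,+10,+14,+17,+18,+21,+21[9]",excluded,Ph-positive exact breakpoints
"54,XY,t(9;22)(q34;q11.2),+4,+6,+10,+14,+17,+18,+21,+21[9]",excluded,Ph-positive sub-band refinement
"56,XX,+5,+5,+8,+8,+10,+10,+14,+14,+18,+18[20]",excluded,masked doubled hypodiploid: five tetrasomies all-even
"55,XY,+4,+6,+10,+14,+17,+18,+21,+21,+21[10]/56,idem,+5[4]",D-GR,stemline first in document order
"51,XX,+X,+10,+14,+21,+mar[15]",P-PR,marker; no profile gains seen; baseline poor
"67,XX,+X,+2,+3,+4,+5,+6,+7,+8,+9,+10,+11,+12,+13,+14,+16,+17,+18,+20,+21,+21,+22[5]",D-PR,upper modal bound; +5 and +20 both present
"68,XX,+X,+2,+3,+4,+5,+6,+7,+8,+9,+10,+11,+12,+13,+14,+15,+16,+17,+18,+19,+20,+21,+22[4]",not_heh,modal 68 above range
"50,XX,+4,+6,+10,+21[20]",not_heh,modal 50 below range
"51-56,XX,+4,+6,+14,+17,+18,+21,inc[cp10]",P-GR,count range plus composite plus inc
"56,XX,+X,+4,+6,+10,+14,+17,+18,+20,+21,?+5[12]",P-GR,question-mark gain leaves chromosome 5 uncertain
"55,XX,+X,+4,+6,+10,+14,+17,+18,+21,+21[18]",D-GR,fully certain good-risk pattern
"55,XY,+5,+6,+8,+10,+14,+20,+21,+21,+X[7]",D-PR,+5 and +20 without +17/+18
"52,XY,+5,+6,+8,+10,+14,+21[20]",D-PR,+5 alone; no +17/+18
"51,XX,+4,+6,+10,+14,+21[20]",D-PR,no profile chromosome gained
"53,XY,+X,+6,+10,+14,+17,+21,+21[20]",D-GR,+17 alone
"53,XY,+X,+6,+10,+14,+18,+21,+21[20]",D-GR,+18 alone
"54,XY,+X,+5,+6,+10,+14,+17,+21,+21[20]",D-GR,+5 with +17 but no +20
"54,XY,+X,+6,+10,+14,+17,+20,+21,+21[20]",D-GR,+20 with +17 but no +5
"55,XY,+X,+5,+6,+10,+14,+17,+20,+21,+21[20]",D-PR,+5 and +20 override +17
"56,XX,+X,+4,+5,+6,+10,+14,+17,+18,+20,+21[10]",D-PR,all four profile chromosomes gained
"55,XX,+X,+4,+5,+6,+10,+14,+17,+18,+21[10]",D-GR,+5 with both +17 and +18 but no +20
"52,XX,+4,+6,+14,+17,+18,+mar[10]",P-GR,marker with +17+18 certain; 5/20 uncertain
"52,XX,+4,+6,+10,+14,+21,+mar[10]",P-PR,marker; baseline resolution has no profile gain
"53,XX,+4,+5,+6,+14,+20,+21,+mar[10]",D-PR,marker but every resolution poor: +5 and +20 certain
"53,XX,+4,+6,+14,+17,+18,+21,+mar[10]",P-GR,marker softens definite good to provisional
"46,XX,t(9;22)(q34;q11)[20]",not_heh,Ph-positive but modal outside range: eligibility first
"55,XY,+X,+4,+6,+10,+14,+17,+18,+21,+21,del(6)(q21)[12]",D-GR,structural deletion adds no whole-chromosome change
"54,XX,+X,+4,+6,+10,+14,+17,+18,+21c[20]",D-GR,constitutional gain counted with warning
"52,XX,+4,+6,+10,+14,+17,+18,+21,-9[20]",D-GR,whole-chromosome loss applied to profile
"55,XY,+4,+6,+10,+14,+17,+18,+21,+21,+unknown1[10]",D-GR,unrecognised token preserved with warning only
"99,XXXX,+1,+2[2]",not_heh,near-tetraploid modal above range
"45,X[20]",not_heh,monosomy X below range
"XX,+4,+6",error,missing leading chromosome count
"abc",error,not a karyotype
"57,XX,+X,+4,+6,+10,+14,+17,+18,+21,+21,+mar[12]/46,XX[8]",P-GR,marker in the HeH clone softens to provisional
"46,XY[10]/55,XY,+4,+6,+10,+14,+17,+18,+21,+21,+X[15]",D-GR,HeH clone listed second is still selected
"51~56,XX,+4,+6,+14,+17,+18,+21[cp10]",D-GR,tilde count range and composite without ambiguity
"55,XY,+4,+6,+10,+14,+17,+18,+21,+21,+21[10]/56,idem,+mar[4]",D-GR,first in-range clone has no marker
"46,XX[5]/52,XX,+4,+6,+10,+17,+18,+21[8]/53,idem,+mar[3]",D-GR,first in-range clone among three
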