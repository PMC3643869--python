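pair,criterion,a,b,c,d
VU-MN,Avoidant,14,0,0,5
VU-MN,Dependent,17,1,0,1
VU-MN,Obsessive-Compulsive,12,1,0,6
VU-MN,Passive-Aggressive,15,0,0,4
VU-MN,Depressive,15,1,1,2
VU-MN,Paranoid,13,0,0,6
VU-MN,Schizotypal,18,0,0,1
VU-MN,Schizoid,13,2,1,3
VU-MN,Histrionic,17,1,0,1
VU-MN,Narcissistic,19,0,0,0
VU-MN,Borderline,15,0,0,4
VU-MN,Antisocial,16,1,1,1
US-SP,Avoidant,13,0,0,3
US-SP,Dependent,15,0,0,1
US-SP,Obsessive-Compulsive,10,0,2,4
US-SP,Passive-Aggressive,14,0,1,1
US-SP,Depressive,13,1,0,2
US-SP,Paranoid,15,0,0,1
US-SP,Schizotypal,16,0,0,0
US-SP,Schizoid,15,0,0,1
US-SP,Histrionic,15,0,0,1
US-SP,Narcissistic,16,0,0,0
US-SP,Borderline,14,0,0,2
US-SP,Antisocial,15,0,0,1
TW-SR,Avoidant,9,0,0,1
TW-SR,Dependent,9,1,0,0
TW-SR,Obsessive-Compulsive,8,0,0,2
TW-SR,Passive-Aggressive,9,0,1,0
TW-SR,Depressive,10,0,0,0
TW-SR,Paranoid,9,0,1,0
TW-SR,Schizotypal,9,0,0,1
TW-SR,Schizoid,7,1,0,2
TW-SR,Histrionic,10,0,0,0
TW-SR,Narcissistic,9,0,0,1
TW-SR,Borderline,8,1,0,1
TW-SR,Antisocial,10,0,0,0
NW-SR,Avoidant,7,1,0,0
NW-SR,Dependent,7,0,0,1
NW-SR,Obsessive-Compulsive,6,0,0,2
NW-SR,Passive-Aggressive,6,1,0,1
NW-SR,Depressive,7,0,0,1
NW-SR,Paranoid,8,0,0,0
NW-SR,Schizotypal,8,0,0,0
NW-SR,Schizoid,6,0,1,1
NW-SR,Histrionic,8,0,0,0
NW-SR,Narcissistic,8,0,0,0
NW-SR,Borderline,7,0,0,1
NW-SR,Antisocial,7,0,0,1
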