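cog_code	genome_count
J	164
A	2
K	370
L	200
B	2
D	38
V	61
T	232
M	253
N	120
U	37
O	165
C	274
G	200
E	480
F	87
H	163
I	178
P	257
Q	79
R	464
S	420
–	1104
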