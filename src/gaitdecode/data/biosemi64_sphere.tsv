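label	x	y	z
Fp1	80.790558460780	26.250443713563	-2.966457219713
AF7	68.724553861875	49.931311098847	-2.966457219713
AF3	74.051911634761	34.530973496306	23.429175244445
F1	60.372443360944	24.392050435569	54.636946823356
F3	57.207392330969	46.325632890341	42.500000000000
F5	53.864870572125	61.964445365221	21.999618833714
F7	49.931311098847	68.724553861875	-2.966457219713
FT7	26.250443713563	80.790558460780	-2.966457219713
FC5	28.970394759943	75.470458588991	26.266444521871
FC3	30.569066959334	57.492053251363	54.636946823356
FC1	31.850307943758	31.850307943758	72.084088173296
C1	0.000000000000	33.212145921588	78.242912543457
C3	0.000000000000	61.143883028785	59.045961489015
C5	0.000000000000	79.354336252262	30.461275711351
T7	0.000000000000	84.948220296623	-2.966457219713
TP7	-26.250443713563	80.790558460780	-2.966457219713
CP5	-28.970394759943	75.470458588991	26.266444521871
CP3	-30.569066959334	57.492053251363	54.636946823356
CP1	-31.850307943758	31.850307943758	72.084088173296
P1	-60.372443360944	24.392050435569	54.636946823356
P3	-57.207392330969	46.325632890341	42.500000000000
P5	-53.864870572125	61.964445365221	21.999618833714
P7	-49.931311098847	68.724553861875	-2.966457219713
P9	-45.280719856927	62.323564156995	-35.922552247959
PO7	-68.724553861875	49.931311098847	-2.966457219713
PO3	-74.051911634761	34.530973496306	23.429175244445
O1	-80.790558460780	26.250443713563	-2.966457219713
Iz	-77.036161898115	0.000000000000	-35.922552247959
Oz	-84.948220296623	0.000000000000	-2.966457219713
POz	-79.354336252262	0.000000000000	30.461275711351
Pz	-61.143883028785	0.000000000000	59.045961489015
CPz	-33.212145921588	0.000000000000	78.242912543457
Fpz	84.948220296623	0.000000000000	-2.966457219713
Fp2	80.790558460780	-26.250443713563	-2.966457219713
AF8	68.724553861875	-49.931311098847	-2.966457219713
AF4	74.051911634761	-34.530973496306	23.429175244445
AFz	79.354336252262	0.000000000000	30.461275711351
Fz	61.143883028785	0.000000000000	59.045961489015
F2	60.372443360944	-24.392050435569	54.636946823356
F4	57.207392330969	-46.325632890341	42.500000000000
F6	53.864870572125	-61.964445365221	21.999618833714
F8	49.931311098847	-68.724553861875	-2.966457219713
FT8	26.250443713563	-80.790558460780	-2.966457219713
FC6	28.970394759943	-75.470458588991	26.266444521871
FC4	30.569066959334	-57.492053251363	54.636946823356
FC2	31.850307943758	-31.850307943758	72.084088173296
FCz	33.212145921588	0.000000000000	78.242912543457
Cz	0.000000000000	0.000000000000	85.000000000000
C2	0.000000000000	-33.212145921588	78.242912543457
C4	0.000000000000	-61.143883028785	59.045961489015
C6	0.000000000000	-79.354336252262	30.461275711351
T8	0.000000000000	-84.948220296623	-2.966457219713
TP8	-26.250443713563	-80.790558460780	-2.966457219713
CP6	-28.970394759943	-75.470458588991	26.266444521871
CP4	-30.569066959334	-57.492053251363	54.636946823356
CP2	-31.850307943758	-31.850307943758	72.084088173296
P2	-60.372443360944	-24.392050435569	54.636946823356
P4	-57.207392330969	-46.325632890341	42.500000000000
P6	-53.864870572125	-61.964445365221	21.999618833714
P8	-49.931311098847	-68.724553861875	-2.966457219713
P10	-45.280719856927	-62.323564156995	-35.922552247959
PO8	-68.724553861875	-49.931311098847	-2.966457219713
PO4	-74.051911634761	-34.530973496306	23.429175244445
O2	-80.790558460780	-26.250443713563	-2.966457219713
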