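id,sire,dam
1E,0,0
2E,0,0
3E,0,0
4E,0,0
10E,0,0
14E,0,0
16E,0,0
1M,0,0
3M,0,0
11M,0,0
17M,0,0
21M,0,0
22M,0,0
23M,0,0
2L,0,0
3L,0,0
6L,0,0
12L,0,0
15L,0,0
20L,0,0
25L,0,0
F01-1,2E,1E
F01-2,2E,1E
F02-1,4E,1E
F03-1,1M,1E
F03-2,1M,1E
F03-3,1M,1E
F03-4,1M,1E
F03-5,1M,1E
F03-6,1M,1E
F04-1,10E,3E
F04-2,10E,3E
F05-1,14E,3E
F05-2,14E,3E
F06-1,1M,3E
F07-1,11M,3E
F07-2,11M,3E
F07-3,11M,3E
F08-1,11M,4E
F08-2,11M,4E
F09-1,17M,4E
F09-2,17M,4E
F09-3,17M,4E
F10-1,1M,10E
F10-2,1M,10E
F10-3,1M,10E
F10-4,1M,10E
F10-5,1M,10E
F11-1,1E,14E
F12-1,2E,14E
F12-2,2E,14E
F12-3,2E,14E
F12-4,2E,14E
F12-5,2E,14E
F12-6,2E,14E
F12-7,2E,14E
F12-8,2E,14E
F12-9,2E,14E
F12-10,2E,14E
F12-11,2E,14E
F13-1,25L,14E
F13-2,25L,14E
F14-1,11M,14E
F14-2,11M,14E
F14-3,11M,14E
F14-4,11M,14E
F14-5,11M,14E
F14-6,11M,14E
F15-1,21M,1M
F15-2,21M,1M
F15-3,21M,1M
F16-1,2E,3M
F16-2,2E,3M
F16-3,2E,3M
F17-1,1M,3M
F17-2,1M,3M
F17-3,1M,3M
F17-4,1M,3M
F18-1,6L,3M
F19-1,2E,11M
F19-2,2E,11M
F19-3,2E,11M
F19-4,2E,11M
F19-5,2E,11M
F19-6,2E,11M
F19-7,2E,11M
F19-8,2E,11M
F19-9,2E,11M
F20-1,16E,11M
F21-1,1M,11M
F22-1,1M,17M
F22-2,1M,17M
F22-3,1M,17M
F22-4,1M,17M
F22-5,1M,17M
F22-6,1M,17M
F22-7,1M,17M
F23-1,2L,17M
F24-1,14E,21M
F24-2,14E,21M
F25-1,1M,21M
F25-2,1M,21M
F25-3,1M,21M
F26-1,11M,21M
F26-2,11M,21M
F27-1,6L,21M
F28-1,4E,22M
F28-2,4E,22M
F29-1,10E,22M
F30-1,1M,22M
F30-2,1M,22M
F31-1,21M,22M
F32-1,14E,23M
F32-2,14E,23M
F33-1,17M,23M
F33-2,17M,23M
F34-1,3L,23M
F34-2,3L,23M
F35-1,15L,23M
F36-1,1E,6L
F36-2,1E,6L
F37-1,1M,6L
F38-1,1E,12L
F38-2,1E,12L
F38-3,1E,12L
F38-4,1E,12L
F38-5,1E,12L
F38-6,1E,12L
F39-1,1M,12L
F39-2,1M,12L
F39-3,1M,12L
F39-4,1M,12L
F40-1,2L,12L
F40-2,2L,12L
F40-3,2L,12L
F41-1,4E,20L
F41-2,4E,20L
F41-3,4E,20L
F41-4,4E,20L
F42-1,14E,20L
F42-2,14E,20L
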