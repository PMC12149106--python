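# Default stopword list for policy-text mining. One term per line; lines
# starting with '#' are comments. The list mixes common Latin function
# words with Chinese particles and light verbs that carry no policy
# content. It is deliberately small and meant to be edited per corpus.
a
an
and
are
as
at
be
by
for
from
has
have
in
is
it
its
of
on
or
shall
should
that
the
this
to
was
were
will
with
的
了
和
与
及
等
在
是
为
于
对
以
或
被
其
该
各
并
但
而
即
如
之
这
那
把
向
从
就
也
都
很
不
应当
可以
有关
按照
根据
以及
进行
相关
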